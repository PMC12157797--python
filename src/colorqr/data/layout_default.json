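{
 "canvas_w": 720,
 "canvas_h": 400,
 "qr": {
  "x": 50,
  "y": 55,
  "module_px": 10,
  "modules": 29
 },
 "window": {
  "x": 390,
  "y": 40,
  "w": 300,
  "h": 320
 }
}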