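[
 {
  "id": "white",
  "rgb": [
   255,
   255,
   255
  ]
 },
 {
  "id": "gray80",
  "rgb": [
   204,
   204,
   204
  ]
 },
 {
  "id": "gray60",
  "rgb": [
   153,
   153,
   153
  ]
 },
 {
  "id": "gray40",
  "rgb": [
   102,
   102,
   102
  ]
 },
 {
  "id": "gray20",
  "rgb": [
   51,
   51,
   51
  ]
 },
 {
  "id": "black",
  "rgb": [
   0,
   0,
   0
  ]
 },
 {
  "id": "btb0",
  "rgb": [
   235,
   235,
   180
  ]
 },
 {
  "id": "btb1",
  "rgb": [
   210,
   225,
   170
  ]
 },
 {
  "id": "btb2",
  "rgb": [
   170,
   210,
   170
  ]
 },
 {
  "id": "btb3",
  "rgb": [
   120,
   190,
   180
  ]
 },
 {
  "id": "btb4",
  "rgb": [
   80,
   160,
   185
  ]
 },
 {
  "id": "btb5",
  "rgb": [
   50,
   120,
   180
  ]
 },
 {
  "id": "btb6",
  "rgb": [
   30,
   80,
   160
  ]
 },
 {
  "id": "btb7",
  "rgb": [
   15,
   45,
   120
  ]
 },
 {
  "id": "red",
  "rgb": [
   220,
   40,
   40
  ]
 },
 {
  "id": "green",
  "rgb": [
   40,
   200,
   60
  ]
 },
 {
  "id": "blue",
  "rgb": [
   30,
   60,
   200
  ]
 },
 {
  "id": "cyan",
  "rgb": [
   40,
   200,
   200
  ]
 },
 {
  "id": "magenta",
  "rgb": [
   200,
   40,
   180
  ]
 },
 {
  "id": "yellow",
  "rgb": [
   230,
   220,
   40
  ]
 },
 {
  "id": "orange",
  "rgb": [
   240,
   150,
   40
  ]
 },
 {
  "id": "purple",
  "rgb": [
   120,
   50,
   160
  ]
 },
 {
  "id": "teal",
  "rgb": [
   20,
   130,
   120
  ]
 },
 {
  "id": "brown",
  "rgb": [
   140,
   90,
   50
  ]
 }
]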