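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
  "id": "dpd0",
  "rgb": [
   250,
   245,
   245
  ]
 },
 {
  "id": "dpd1",
  "rgb": [
   245,
   220,
   225
  ]
 },
 {
  "id": "dpd2",
  "rgb": [
   240,
   190,
   205
  ]
 },
 {
  "id": "dpd3",
  "rgb": [
   235,
   160,
   185
  ]
 },
 {
  "id": "dpd4",
  "rgb": [
   225,
   130,
   165
  ]
 },
 {
  "id": "dpd5",
  "rgb": [
   210,
   100,
   145
  ]
 },
 {
  "id": "dpd6",
  "rgb": [
   190,
   70,
   125
  ]
 },
 {
  "id": "dpd7",
  "rgb": [
   160,
   40,
   100
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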