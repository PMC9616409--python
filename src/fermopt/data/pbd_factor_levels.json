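[
 {
  "name": "peptone",
  "unit": "g/l",
  "center": 5.0,
  "step": 4.0,
  "alpha": 2.0
 },
 {
  "name": "yeast_extract",
  "unit": "g/l",
  "center": 2.0,
  "step": 1.0,
  "alpha": 2.0
 },
 {
  "name": "beef_extract",
  "unit": "g/l",
  "center": 3.0,
  "step": 2.0,
  "alpha": 2.0
 },
 {
  "name": "nacl",
  "unit": "g/l",
  "center": 5.0,
  "step": 5.0,
  "alpha": 2.0
 },
 {
  "name": "glucose",
  "unit": "g/l",
  "center": 1.0,
  "step": 0.5,
  "alpha": 2.0
 },
 {
  "name": "mgso4",
  "unit": "g/l",
  "center": 1.0,
  "step": 0.5,
  "alpha": 2.0
 },
 {
  "name": "ph",
  "unit": "",
  "center": 7.0,
  "step": 3.0,
  "alpha": 2.0
 },
 {
  "name": "temperature",
  "unit": "degC",
  "center": 35.0,
  "step": 5.0,
  "alpha": 2.0
 },
 {
  "name": "agitation",
  "unit": "rpm",
  "center": 120.0,
  "step": 30.0,
  "alpha": 2.0
 },
 {
  "name": "inoculum_size",
  "unit": "%",
  "center": 1.0,
  "step": 0.5,
  "alpha": 2.0
 },
 {
  "name": "incubation_period",
  "unit": "h",
  "center": 48.0,
  "step": 24.0,
  "alpha": 2.0
 }
]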