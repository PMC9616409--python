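[
 {
  "name": "peptone",
  "unit": "g/l",
  "center": 7.5,
  "step": 1.25,
  "alpha": 2.0
 },
 {
  "name": "temperature",
  "unit": "degC",
  "center": 33.5,
  "step": 1.75,
  "alpha": 2.0
 },
 {
  "name": "agitation",
  "unit": "rpm",
  "center": 160.0,
  "step": 20.0,
  "alpha": 2.0
 },
 {
  "name": "inoculum_size",
  "unit": "%",
  "center": 2.0,
  "step": 0.5,
  "alpha": 2.0
 }
]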