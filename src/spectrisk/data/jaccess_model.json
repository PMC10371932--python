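{
  "intercept": -4.8125,
  "coefficients": {
    "diabetes": 0.8858,
    "age": 0.0558,
    "sss": 0.1941,
    "lvef": -0.0475
  },
  "transforms": {
    "sss": "sss_category"
  },
  "scale": "fraction"
}
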