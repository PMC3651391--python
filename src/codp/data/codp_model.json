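{
  "intercept": -3.7273,
  "coefficients": {
    "mapp_norm": 0.1581,
    "sift": -1.2824,
    "pph2_humvar": 4.6733,
    "delta_heavy": 1.0475,
    "rel_acc": -8.0548
  }
}
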