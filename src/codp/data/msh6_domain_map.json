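{
  "default_threshold": 8.5,
  "domains": [
    {"name": "PCNA-binding motif", "start": 4, "end": 11, "threshold": 4.1},
    {"name": "PWWP", "start": 89, "end": 194, "threshold": 5.0},
    {"name": "MutS", "start": 362, "end": 1355, "threshold": 4.1}
  ]
}
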