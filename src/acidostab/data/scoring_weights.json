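{
  "x_K": 0.68,
  "x_small": 0.75,
  "x_T": 0.9,
  "x_tiny": 0.58,
  "x_aliphatic": -0.97,
  "x_aromatic": -0.74,
  "x_I": -0.96,
  "x_LQ": -0.04,
  "x_Q": -0.01,
  "x_Y": -0.53
}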