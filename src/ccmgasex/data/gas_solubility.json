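{
  "CO2": {"H298": 0.035, "B": 2400.0},
  "O2": {"H298": 0.0012, "B": 1700.0}
}
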