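{
  "base": {"nh3": 10.0, "co2": 10.0},
  "glucose_uptake": {"high": 2.78, "low": 0.1},
  "supplement_uptake": 10.0
}
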