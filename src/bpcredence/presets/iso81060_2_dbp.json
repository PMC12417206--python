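{
  "name": "iso81060_2_dbp",
  "description": "ISO 81060-2 style acceptance parameters for diastolic blood pressure",
  "params": {
    "c_pmin": 0.95,
    "p_test": 0.78,
    "delta": 10.0,
    "p_hat": 0.85,
    "ref_mean": 80.0,
    "ref_sd": 13.0
  },
  "tail_requirements": [
    {"threshold": 60.0, "side": "below", "min_fraction": 0.05},
    {"threshold": 100.0, "side": "above", "min_fraction": 0.05},
    {"threshold": 85.0, "side": "above", "min_fraction": 0.20}
  ]
}
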