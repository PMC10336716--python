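{
  "name": "gusto_mortality_30d",
  "intercept": -2.084,
  "terms": [
    {"name": "age", "coefficient": 0.078, "transform": "identity"},
    {"name": "ami_location_other", "coefficient": 0.403, "transform": "identity"},
    {"name": "anterior_ami", "coefficient": 0.577, "transform": "identity"},
    {"name": "previous_ami", "coefficient": 0.468, "transform": "identity"},
    {"name": "killip_score", "coefficient": 0.767, "transform": "identity"},
    {"name": "blood_pressure", "coefficient": -0.077, "transform": {"type": "min_cap", "cap": 100}},
    {"name": "pulse", "coefficient": 0.018, "transform": "identity"}
  ]
}
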