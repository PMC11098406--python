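{
 "baseline": [
  -3.06,
  0.10259,
  0.0
 ],
 "hazard_ratios": {
  "baseline_age": 1.108,
  "baseline_gcp": 0.927,
  "education_high_school_grad": 0.919,
  "education_less_than_high_school": 1.032,
  "education_some_college": 0.797,
  "education_some_high_school": 1.088,
  "gcp_slope": 0.999,
  "race_nh_black": 1.214,
  "sex_female": 1.1
 },
 "references": {
  "baseline_age": 75.0,
  "baseline_gcp": 50.0
 }
}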