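{
 "coefficients": {
  "age": 0.01,
  "intercept": -5.30411985013459,
  "lag_other_lipid_agent": 5.0
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_other_lipid_agent": "lagged"
 },
 "family": "logistic",
 "name": "other_lipid_use",
 "outcome": "other_lipid_agent",
 "residual": {
  "mean": 0.0,
  "sd": 0.0
 },
 "transform": "none"
}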