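{
 "coefficients": {
  "age": 0.02,
  "intercept": -5.769820298110627,
  "lag_statin": 6.0
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_statin": "lagged"
 },
 "family": "logistic",
 "name": "statin_use",
 "outcome": "statin",
 "residual": {
  "mean": 0.0,
  "sd": 0.0
 },
 "transform": "none"
}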