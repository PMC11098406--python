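{
 "coefficients": {
  "age": 0.01,
  "intercept": -3.9350986898352733
 },
 "covariate_kinds": {
  "age": "lagged"
 },
 "family": "logistic",
 "name": "smoking_quit",
 "outcome": "smoking_status",
 "residual": {
  "mean": 0.0,
  "sd": 0.0
 },
 "transform": "none"
}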