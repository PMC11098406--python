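{
 "coefficients": {
  "age": 0.01,
  "intercept": -13.95886238757714,
  "lag_log_sbp": 2.0
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_log_sbp": "lagged"
 },
 "family": "logistic",
 "name": "antihypertensive_add",
 "outcome": "n_antihypertensives",
 "residual": {
  "mean": 0.0,
  "sd": 0.0
 },
 "transform": "none"
}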