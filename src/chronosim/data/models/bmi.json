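{
 "coefficients": {
  "age": 0.00040000000000000034,
  "intercept": 0.5516400000000005,
  "lag_bmi": 0.7,
  "lagmean_bmi": 0.28
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lagmean_bmi": "lagged_mean"
 },
 "family": "linear",
 "name": "bmi",
 "outcome": "bmi",
 "residual": {
  "mean": 0.0,
  "sd": 1.3
 },
 "transform": "none"
}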