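{
 "coefficients": {
  "age": 0.0040000000000000036,
  "intercept": 1.9077200000000016,
  "lag_bmi": 0.008000000000000007,
  "lag_ldl": 0.7,
  "lagmean_ldl": 0.28,
  "sex_male": -0.040000000000000036
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lag_ldl": "lagged",
  "lagmean_ldl": "lagged_mean",
  "sex_male": "static"
 },
 "family": "linear",
 "name": "ldl",
 "outcome": "ldl",
 "residual": {
  "mean": 0.0,
  "sd": 7.0
 },
 "transform": "none"
}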