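{
 "coefficients": {
  "age": 0.006000000000000005,
  "intercept": 3.4079000000000033,
  "lag_bmi": 0.010000000000000009,
  "lag_total_chol": 0.7,
  "lagmean_total_chol": 0.28,
  "sex_male": -0.10000000000000009
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lag_total_chol": "lagged",
  "lagmean_total_chol": "lagged_mean",
  "sex_male": "static"
 },
 "family": "linear",
 "name": "total_chol",
 "outcome": "total_chol",
 "residual": {
  "mean": 0.0,
  "sd": 8.0
 },
 "transform": "none"
}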