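{
 "coefficients": {
  "age": 0.00020000000000000017,
  "intercept": 0.08526000000000006,
  "lag_a1c": 0.7,
  "lag_bmi": 0.0006000000000000005,
  "lagmean_a1c": 0.28,
  "race_nh_black": 0.0040000000000000036
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_a1c": "lagged",
  "lag_bmi": "lagged",
  "lagmean_a1c": "lagged_mean",
  "race_nh_black": "static"
 },
 "family": "linear",
 "name": "a1c",
 "outcome": "a1c",
 "residual": {
  "mean": 0.0,
  "sd": 0.18
 },
 "transform": "none"
}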