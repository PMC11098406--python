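{
 "coefficients": {
  "age": -0.0010000000000000009,
  "intercept": 0.13624000000000014,
  "lag_physical_activity": 0.7,
  "lagmean_physical_activity": 0.28,
  "sex_male": 0.020000000000000018
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_physical_activity": "lagged",
  "lagmean_physical_activity": "lagged_mean",
  "sex_male": "static"
 },
 "family": "linear",
 "name": "physical_activity",
 "outcome": "physical_activity",
 "residual": {
  "mean": 0.0,
  "sd": 0.7
 },
 "transform": "none"
}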