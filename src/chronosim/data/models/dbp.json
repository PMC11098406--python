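{
 "coefficients": {
  "age": -2.000000000000002e-05,
  "intercept": 0.08464472238032118,
  "lag_bmi": 6.0000000000000056e-05,
  "lag_log_dbp": 0.7,
  "lagmean_log_dbp": 0.28,
  "sex_male": 0.00020000000000000017
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lag_log_dbp": "lagged",
  "lagmean_log_dbp": "lagged_mean",
  "sex_male": "static"
 },
 "family": "linear",
 "name": "dbp",
 "outcome": "dbp",
 "residual": {
  "mean": 0.0,
  "sd": 0.025
 },
 "transform": "log-outcome"
}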