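{
 "coefficients": {
  "age": 6.600000000000006e-05,
  "intercept": 0.09046882089466521,
  "lag_bmi": 8.000000000000007e-05,
  "lag_log_sbp": 0.7,
  "lagmean_log_sbp": 0.28,
  "race_nh_black": 0.0006000000000000005,
  "sex_male": 0.00040000000000000034,
  "smoking_current": 0.00020000000000000017
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lag_log_sbp": "lagged",
  "lagmean_log_sbp": "lagged_mean",
  "race_nh_black": "static",
  "sex_male": "static",
  "smoking_current": "indicator"
 },
 "family": "linear",
 "name": "sbp",
 "outcome": "sbp",
 "residual": {
  "mean": 0.0,
  "sd": 0.025
 },
 "transform": "log-outcome"
}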