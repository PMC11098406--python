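{
 "coefficients": {
  "intercept": -8.8367234212961,
  "lag_a1c": 0.05,
  "lag_age": 0.015,
  "lag_bmi": -0.01,
  "lag_log_dbp": 0.5,
  "lag_log_sbp": 1.2,
  "lag_trig": -0.001,
  "race_hispanic": 0.05,
  "race_nh_black": 0.35,
  "race_other": 0.0,
  "sex_male": -0.15
 },
 "covariate_kinds": {
  "lag_a1c": "lagged",
  "lag_age": "lagged",
  "lag_bmi": "lagged",
  "lag_log_dbp": "lagged",
  "lag_log_sbp": "lagged",
  "lag_trig": "lagged",
  "race_hispanic": "static",
  "race_nh_black": "static",
  "race_other": "static",
  "sex_male": "static"
 },
 "family": "logistic",
 "name": "stroke_partition",
 "outcome": "stroke_partition",
 "residual": {
  "mean": 0.0,
  "sd": 0.0
 },
 "transform": "none"
}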