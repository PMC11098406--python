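{
 "coefficients": {
  "age": 0.085,
  "age_squared": 0.0002,
  "intercept": -12.361051044747704,
  "lag_a1c": 0.1,
  "lag_bmi": 0.01,
  "lag_total_chol": 0.0005,
  "lag_trig": 0.0002,
  "lagmean_dbp": -0.002,
  "lagmean_sbp": 0.004,
  "race_hispanic": -0.1,
  "race_nh_black": 0.15,
  "race_other": 0.0,
  "sex_male": 0.25,
  "smoking_current": 0.5
 },
 "covariate_kinds": {
  "age": "current",
  "age_squared": "current",
  "lag_a1c": "lagged",
  "lag_bmi": "lagged",
  "lag_total_chol": "lagged",
  "lag_trig": "lagged",
  "lagmean_dbp": "lagged_mean",
  "lagmean_sbp": "lagged_mean",
  "race_hispanic": "static",
  "race_nh_black": "static",
  "race_other": "static",
  "sex_male": "static",
  "smoking_current": "indicator"
 },
 "family": "logistic",
 "name": "non_cv_mortality",
 "outcome": "non_cv_mortality",
 "residual": {
  "mean": 0.0,
  "sd": 0.0
 },
 "transform": "none"
}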