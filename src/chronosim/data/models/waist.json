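{
 "coefficients": {
  "age": 0.0020000000000000018,
  "intercept": 0.6309200000000006,
  "lag_bmi": 0.040000000000000036,
  "lag_waist": 0.7,
  "lagmean_waist": 0.28,
  "sex_male": 0.16000000000000014
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lag_waist": "lagged",
  "lagmean_waist": "lagged_mean",
  "sex_male": "static"
 },
 "family": "linear",
 "name": "waist",
 "outcome": "waist",
 "residual": {
  "mean": 0.0,
  "sd": 3.2
 },
 "transform": "none"
}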