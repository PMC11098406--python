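{
 "coefficients": {
  "age": 0.010000000000000009,
  "intercept": 0.8561000000000007,
  "lag_bmi": 0.040000000000000036,
  "lag_trig": 0.7,
  "lagmean_trig": 0.28,
  "sex_male": 0.30000000000000027
 },
 "covariate_kinds": {
  "age": "lagged",
  "lag_bmi": "lagged",
  "lag_trig": "lagged",
  "lagmean_trig": "lagged_mean",
  "sex_male": "static"
 },
 "family": "linear",
 "name": "trig",
 "outcome": "trig",
 "residual": {
  "mean": 0.0,
  "sd": 18.0
 },
 "transform": "none"
}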