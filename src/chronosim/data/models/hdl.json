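{
 "coefficients": {
  "intercept": 1.3772800000000012,
  "lag_bmi": -0.008000000000000007,
  "lag_hdl": 0.7,
  "lagmean_hdl": 0.28,
  "sex_male": -0.16000000000000014,
  "smoking_current": -0.06000000000000005
 },
 "covariate_kinds": {
  "lag_bmi": "lagged",
  "lag_hdl": "lagged",
  "lagmean_hdl": "lagged_mean",
  "sex_male": "static",
  "smoking_current": "indicator"
 },
 "family": "linear",
 "name": "hdl",
 "outcome": "hdl",
 "residual": {
  "mean": 0.0,
  "sd": 3.0
 },
 "transform": "none"
}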