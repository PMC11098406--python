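{
 "female_black": {
  "a1c": 0.2,
  "age": 0.075,
  "hdl": -0.012,
  "intercept": -10.402347035369203,
  "sbp_treated": 0.018,
  "sbp_untreated": 0.018,
  "smoking_current": 0.55,
  "total_chol": 0.003
 },
 "female_nonblack": {
  "a1c": 0.2,
  "age": 0.075,
  "hdl": -0.012,
  "intercept": -10.71153531304195,
  "sbp_treated": 0.018,
  "sbp_untreated": 0.018,
  "smoking_current": 0.55,
  "total_chol": 0.003
 },
 "male_black": {
  "a1c": 0.2,
  "age": 0.075,
  "hdl": -0.012,
  "intercept": -9.952430164690206,
  "sbp_treated": 0.018,
  "sbp_untreated": 0.018,
  "smoking_current": 0.55,
  "total_chol": 0.003
 },
 "male_nonblack": {
  "a1c": 0.2,
  "age": 0.075,
  "hdl": -0.012,
  "intercept": -10.157224577336219,
  "sbp_treated": 0.018,
  "sbp_untreated": 0.018,
  "smoking_current": 0.55,
  "total_chol": 0.003
 }
}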