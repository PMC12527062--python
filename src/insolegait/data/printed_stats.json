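{
  "mann_whitney_u": {
    "stride_approach1_vs_approach2_right": 31.0,
    "stride_approach1_vs_approach2_left": 30.0,
    "distance_actual_vs_gaitup_right": 25.0,
    "distance_actual_vs_gaitup_left": 27.0,
    "distance_actual_vs_approach1_right": 31.0,
    "distance_actual_vs_approach1_left": 26.0,
    "distance_actual_vs_approach2_right": 28.0,
    "distance_actual_vs_approach2_left": 26.5
  },
  "medians": {
    "actual_distance": 609.44,
    "actual_stride_length": 1.591
  },
  "icc_distance": {
    "gaitup_right": 0.980,
    "gaitup_left": 0.982,
    "approach1_right": 0.992,
    "approach1_left": 0.994,
    "approach2_right": 0.996,
    "approach2_left": 0.991
  },
  "icc_stride": {
    "gaitup_right": 0.977,
    "gaitup_left": 0.987,
    "approach1_right": 0.993,
    "approach1_left": 0.995,
    "approach2_right": 0.991,
    "approach2_left": 0.993
  }
}
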