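{
  "description": "Published summary-table cells that an independent recomputation from the printed per-participant inputs does not reproduce. These cells are reported but excluded from exact regression checks.",
  "cells": [
    {"table": "accuracy_summary", "cell": "P8:approach1_right", "printed": 99.10, "computed": 99.09,
     "note": "last-digit rounding difference"},
    {"table": "accuracy_summary", "cell": "P7:approach1_left", "printed": 99.32, "computed": 99.31,
     "note": "last-digit rounding difference"},
    {"table": "accuracy_summary", "cell": "P8:approach1_left", "printed": 97.76, "computed": 97.77,
     "note": "last-digit rounding difference"},
    {"table": "u_tests", "cell": "distance_actual_vs_approach1_right", "printed": 31.0, "computed": 30.0,
     "note": "rank-counting oracle on the printed distances gives 30.0"},
    {"table": "u_tests", "cell": "distance_actual_vs_approach2_left", "printed": 26.5, "computed": 26.0,
     "note": "rank-counting oracle on the printed distances gives 26.0"},
    {"table": "stride_summary", "cell": "P4:insole_count_left", "printed": 387, "computed": 378,
     "note": "printed left-side distances for P4 are consistent with a count of 378, not 387"},
    {"table": "distance_summary", "cell": "P4:approach1_distance_left", "printed": 575.32, "computed": 589.01,
     "note": "stride length x printed count does not reproduce the printed distance (see P4:insole_count_left)"},
    {"table": "distance_summary", "cell": "P4:approach2_distance_left", "printed": 581.36, "computed": 595.21,
     "note": "stride length x printed count does not reproduce the printed distance (see P4:insole_count_left)"}
  ],
  "excluded_tables": [
    {"table": "stride_length_accuracies", "note": "published stride-length accuracies cannot be reproduced from the printed per-side stride lengths and the published actual stride length"},
    {"table": "interquartiles", "note": "published IQR values are internally inconsistent across text and tables; quantile rule unstated"},
    {"table": "accuracy_summary_medians", "note": "published median rows of the accuracy table are not the medians of the printed cells"}
  ]
}
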