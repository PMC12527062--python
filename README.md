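# insolegait

Model-based stride-length and walk-distance estimation from smart-insole
pressure/acceleration recordings.

A walking bout recorded by an instrumented insole (antero-posterior
acceleration plus plantar pressure channels at 40 Hz) is segmented into gait
cycles from toe-off and heel-strike events; the average stride length is then
estimated against a boundary-constrained cubic reference gait model by one of
two methods, and the total distance walked follows as stride length times
stride count:

* **approach 1 (slope ratio)** — the swing-phase acceleration is fit with a
  straight line per cycle and its slope is compared with the model's
  acceleration slope (the director coefficient `6*c1`);
* **approach 2 (DTW scaling)** — the swing-phase acceleration is aligned with
  the model's by dynamic time warping and the mean alignment cost is scaled
  by the inverse swing-acceleration magnitude.

A statistics layer (accuracy, median/IQR, exact Mann-Whitney U, ICC with
confidence intervals) reproduces per-participant validation tables, and a
synthetic-data module generates insole-like recordings and mocap-like
reference trajectories with exact ground truth.

## Layout

| module | contents |
| --- | --- |
| `insolegait.reference_model` | constrained cubic position model, analytic constructor and data fit |
| `insolegait.event_detection` | toe-off/heel-strike detection, cycle segmentation, mocap event rules |
| `insolegait.stride_estimation` | slope-ratio and DTW estimators, total distance |
| `insolegait.distance_stats` | accuracy, median/IQR, Mann-Whitney U, ICC, validation report |
| `insolegait.synthetic_data` | seeded generators with ground-truth annotations |
| `insolegait.io_cli` | CSV schemas, run configuration, command-line interface |

Published per-participant summary tables are bundled under
`insolegait/data/`, together with a `known_discrepancies.json` manifest
listing the handful of printed cells that an independent recomputation does
not reproduce (these are reported, never asserted).

## Command line

```sh
# synthesize a 20-stride recording with ground truth
insolegait simulate --n-strides 20 --stride-length 1.6 --seed 7 --out-dir sim/

# detect gait events
insolegait detect-events sim/recording.csv --out-dir events/

# estimate stride length and total distance (both methods)
insolegait estimate sim/recording.csv --method both --out-dir est/

# build the validation report from participant summary tables
insolegait validate stride_summary.csv distance_summary.csv --out-dir report/

# regression-check the bundled published tables
insolegait reproduce-tables --out-dir tables/
```

Recording CSV schema: `time_s,ax,ay,az,p_heel,p_toe,p_met1,p_met5` (`ax` is
the antero-posterior acceleration).  Every run writes a `provenance.json`
with the configuration and seed.  Tunables (peak detection, ratio
convention, DTW variant, norm choice, ICC form, quantile rule) can be set in
a YAML config passed via `--config`.

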