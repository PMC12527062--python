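"""Stride-length estimators built on the cubic reference model.

Two estimators are provided:

* slope-ratio ("approach 1"): fit a straight line to the swing-phase
  antero-posterior acceleration of each cycle, take the ratio of its slope
  to the model's director coefficient (6*c1), average the ratios R over
  cycles, and scale the model displacement:  L = Px * mean(R).
* DTW scaling ("approach 2"): align each cycle's swing acceleration with
  the model's by dynamic time warping, average the alignment costs d, scale
  by S = 1/||swing accel|| and the model displacement:  L = Px * mean(d) * S.

Total walked distance is the averaged stride length times the stride count.

By default each swing window is time-normalized (linearly resampled) onto
the model's swing grid before slope fitting and before DTW, so that the
ratio measures amplitude and not cadence; the literal un-normalized variant
is available behind ``normalize_time=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateModelError, InputError, ParameterError
from .event_detection import GaitCycle
from .reference_model import ReferenceModel, model_director_coefficient

__all__ = [
    "StrideEstimate",
    "swing_slope",
    "approach1_stride_length",
    "dtw_distance",
    "scaling_coefficient",
    "approach2_stride_length",
    "total_distance",
]

#: Fraction of the model cycle treated as swing when windowing the model.
DEFAULT_SWING_FRACTION = 0.6

NormKind = Literal["mean_abs", "euclidean", "max_abs"]


@dataclass(frozen=True)
class StrideEstimate:
    """Averaged stride length from one estimator over segmented cycles."""

    method: str  # "approach1" | "approach2"
    per_cycle_values: np.ndarray  # ratios R_i or DTW costs d_i
    stride_length_L: float
    n_cycles: int
    model_stride_Px: float
    mean_R: float | None = None  # approach1 only
    scaling_S: float | None = None  # approach2 only
    E: float | None = None  # approach2 only

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.n_cycles != len(self.per_cycle_values):
            raise InputError("n_cycles must equal len(per_cycle_values) and be >= 1")
        if self.stride_length_L < 0:
            raise InputError("stride_length_L must be >= 0")


def swing_slope(
    swing_accel,
    sample_rate: float | None = None,
    center: bool = True,
    times=None,
) -> float:
    """OLS slope of acceleration against time over a swing window.

    Either pass uniformly sampled values with ``sample_rate`` or explicit
    ``times``.  When ``center`` is set both axes are mean-centered first
    (centering does not change an OLS slope; the flag mirrors the pipeline's
    explicit centering step).
    """
    a = np.asarray(swing_accel, dtype=float)
    if a.size < 2:
        raise InputError(f"need at least 2 samples to fit a slope, got {a.size}")
    if times is not None:
        t = np.asarray(times, dtype=float)
        if t.size != a.size:
            raise InputError("times and swing_accel must share one length")
    elif sample_rate is not None and sample_rate > 0:
        t = np.arange(a.size) / float(sample_rate)
    else:
        raise InputError("provide sample_rate > 0 or explicit times")
    if center:
        t = t - t.mean()
        a = a - a.mean()
    tv = float(np.var(t))
    if tv == 0.0:
        raise InputError("zero time variance; cannot fit a slope")
    tc = t - t.mean()
    return float((tc @ (a - a.mean())) / (tc @ tc))


def _resample(values: np.ndarray, target_times: np.ndarray) -> np.ndarray:
    """Linearly map ``values`` onto the normalized positions of ``target_times``."""
    if values.size == target_times.size:
        # both are uniform grids over their spans, so this is the identity
        return np.asarray(values, dtype=float).copy()
    if values.size == 1:
        return np.full(target_times.size, values[0], dtype=float)
    src = np.linspace(0.0, 1.0, values.size)
    span = target_times[-1] - target_times[0]
    dst = (target_times - target_times[0]) / span if span > 0 else src
    return np.interp(dst, src, values)


def approach1_stride_length(
    cycles: Sequence[GaitCycle],
    model: ReferenceModel,
    ratio_convention: Literal["insole_over_model", "model_over_insole"] = "insole_over_model",
    normalize_time: bool = True,
    swing_fraction: float = DEFAULT_SWING_FRACTION,
    sample_rate: float | None = None,
) -> StrideEstimate:
    """Average stride length from the ratio of acceleration slopes.

    For each cycle the swing acceleration is (optionally) resampled onto the
    model's swing grid, centered, and fit with a straight line; the per-cycle
    ratio is |slope| / |6*c1| under the default convention.  The averaged
    ratio scales the model displacement: L = Px * mean(R).
    """
    if len(cycles) < 1:
        raise InputError("need at least one gait cycle")
    director = model_director_coefficient(model, absolute=True)
    if director == 0.0 or model.model_stride_Px == 0.0:
        raise DegenerateModelError(
            "reference model has zero stride (director coefficient 0); "
            "cannot form a slope ratio"
        )
    rate = sample_rate
    if rate is None:
        rate = cycles[0].sample_rate or model.sample_rate
    grid_t, _ = model.swing_grid(swing_fraction, sample_rate=rate)

    ratios = np.empty(len(cycles))
    for i, cyc in enumerate(cycles):
        if normalize_time:
            a = _resample(cyc.swing_accel, grid_t)
            slope = swing_slope(a, times=grid_t, center=True)
        else:
            slope = swing_slope(cyc.swing_accel, sample_rate=cyc.sample_rate or rate,
                                center=True)
        if slope == 0.0:
            warnings.warn(f"cycle {i}: zero swing slope, ratio set to 0", stacklevel=2)
            ratios[i] = 0.0
        elif ratio_convention == "insole_over_model":
            ratios[i] = abs(slope) / director
        elif ratio_convention == "model_over_insole":
            ratios[i] = director / abs(slope)
        else:
            raise ParameterError(f"unknown ratio_convention {ratio_convention!r}")

    mean_r = float(np.mean(ratios))
    return StrideEstimate(
        method="approach1",
        per_cycle_values=ratios,
        stride_length_L=model.model_stride_Px * mean_r,
        n_cycles=len(cycles),
        model_stride_Px=model.model_stride_Px,
        mean_R=mean_r,
    )


def dtw_distance(a, b) -> float:
    """Cumulative cost of the optimal dynamic-time-warping alignment.

    Classic dynamic programming with absolute-difference local cost,
    unconstrained band and steps {match, insert, delete}; the returned cost
    is un-normalized.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("dtw_distance requires non-empty sequences")
    n, m = x.size, y.size
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    return float(acc[-1, -1])


def scaling_coefficient(swing_accel, norm: NormKind = "mean_abs") -> float:
    """S = 1 / ||swing acceleration|| for the DTW estimator.

    The default norm is the mean absolute value over the swing window;
    ``euclidean`` and ``max_abs`` are selectable alternatives.
    """
    a = np.asarray(swing_accel, dtype=float)
    if a.size == 0:
        raise InputError("swing window is empty")
    if norm == "mean_abs":
        denom = float(np.mean(np.abs(a)))
    elif norm == "euclidean":
        denom = float(np.linalg.norm(a))
    elif norm == "max_abs":
        denom = float(np.max(np.abs(a)))
    else:
        raise ParameterError(f"unknown norm {norm!r}")
    if denom == 0.0:
        raise InputError(
            "swing acceleration is identically zero; scaling coefficient "
            "S = 1/||a|| is undefined"
        )
    return 1.0 / denom


def approach2_stride_length(
    cycles: Sequence[GaitCycle],
    model: ReferenceModel,
    swing_fraction: float = DEFAULT_SWING_FRACTION,
    normalize_time: bool = True,
    norm: NormKind = "mean_abs",
    pooled_scaling: bool = True,
    sample_rate: float | None = None,
) -> StrideEstimate:
    """Average stride length from DTW alignment costs against the model.

    Per cycle, the swing acceleration is aligned with the model's swing
    acceleration (both on the model swing grid when ``normalize_time``);
    the scaling coefficient S is computed once from the pooled raw swing
    windows (per-cycle with ``pooled_scaling=False``), and
    L = Px * mean(d) * S.

    Note: when insole and model accelerations coincide all costs are zero
    and L = 0; this degenerate similarity is warned about, not corrected.
    """
    if len(cycles) < 1:
        raise InputError("need at least one gait cycle")
    rate = sample_rate
    if rate is None:
        rate = cycles[0].sample_rate or model.sample_rate
    grid_t, model_swing = model.swing_grid(swing_fraction, sample_rate=rate)

    pooled = np.concatenate([c.swing_accel for c in cycles])
    costs = np.empty(len(cycles))
    per_cycle_s = np.empty(len(cycles))
    for i, cyc in enumerate(cycles):
        insole = _resample(cyc.swing_accel, grid_t) if normalize_time else cyc.swing_accel
        costs[i] = dtw_distance(model_swing, insole)
        if not pooled_scaling:
            per_cycle_s[i] = scaling_coefficient(cyc.swing_accel, norm=norm)

    if pooled_scaling:
        s = scaling_coefficient(pooled, norm=norm)
        e = float(np.mean(costs)) * s
    else:
        s = float(np.mean(per_cycle_s))
        e = float(np.mean(costs * per_cycle_s))
    if e == 0.0:
        warnings.warn(
            "all DTW costs are zero (insole swing identical to model); the "
            "estimator degenerates to L = 0", stacklevel=2,
        )
    return StrideEstimate(
        method="approach2",
        per_cycle_values=costs,
        stride_length_L=model.model_stride_Px * e,
        n_cycles=len(cycles),
        model_stride_Px=model.model_stride_Px,
        scaling_S=s,
        E=e,
    )


def total_distance(stride_length_L: float, stride_count_Ns: int, ndigits: int = 2) -> float:
    """Total distance Td = L * Ns, rounded half-up to ``ndigits`` decimals.

    Rounding uses exact decimal arithmetic on the printed operands so that
    values match hand-computed tables (e.g. 1.535 * 363 -> 557.21).
    """
    if stride_length_L < 0:
        raise ParameterError("stride length must be >= 0")
    if stride_count_Ns < 0 or int(stride_count_Ns) != stride_count_Ns:
        raise ParameterError("stride count must be a non-negative integer")
    product = Decimal(repr(float(stride_length_L))) * Decimal(int(stride_count_Ns))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(product.quantize(quantum, rounding=ROUND_HALF_UP))
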