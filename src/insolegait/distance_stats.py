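"""Validation statistics: accuracy, median/IQR, Mann-Whitney U, ICC.

These kernels reproduce the per-participant validation tables from a summary
table of stride counts, stride lengths and distances.  The Mann-Whitney U is
computed from midranks (tie-corrected) and reported as min(U1, U2); an exact
permutation p-value is used for small samples and a tie-corrected normal
approximation otherwise.  The ICC is derived from the two-way ANOVA mean
squares with F-based 95% confidence bounds, single measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from math import comb, erf, sqrt
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import rankdata

from .errors import InputError, ParameterError
from .stride_estimation import total_distance

__all__ = [
    "Accuracy",
    "MannWhitneyResult",
    "IccResult",
    "ParticipantTable",
    "ValidationReport",
    "accuracy",
    "median_iqr",
    "mann_whitney_u",
    "icc",
    "build_validation_report",
]

QuantileRule = Literal["weighted_average", "tukey"]
IccForm = Literal["oneway", "twoway_random_abs", "twoway_mixed_consistency"]

#: Interpretation thresholds for ICC point estimates.
ICC_BANDS = (
    (0.90, "excellent"),
    (0.75, "good"),
    (0.50, "moderate"),
)

ESTIMATE_COLUMNS = (
    ("gaitup", "right"), ("gaitup", "left"),
    ("approach1", "right"), ("approach1", "left"),
    ("approach2", "right"), ("approach2", "left"),
)


class Accuracy(NamedTuple):
    rounded: float  # percent, half-up at 2 decimals, for table parity
    percent: float  # unrounded percent


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def accuracy(actual: float, estimated: float) -> Accuracy:
    """Percent agreement: (1 - |actual - estimated| / actual) * 100.

    ``actual`` must be strictly positive.  Note the formula is not symmetric
    in its arguments.
    """
    if actual <= 0:
        raise InputError(f"actual must be > 0, got {actual}")
    pct = (1.0 - abs(actual - estimated) / actual) * 100.0
    return Accuracy(rounded=_round_half_up(pct), percent=pct)


def median_iqr(values, rule: QuantileRule = "weighted_average") -> tuple[float, float]:
    """Sample median and interquartile range Q3 - Q1.

    ``weighted_average`` places quantiles at position (n+1)p (SPSS default,
    Hyndman-Fan type 6); ``tukey`` uses Tukey hinges (medians of the halves,
    including the overall median when n is odd).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise InputError("median_iqr requires a non-empty sequence")
    med = float(np.median(v))
    if v.size == 1:
        return med, 0.0
    if rule == "weighted_average":
        q1, q3 = np.percentile(v, [25, 75], method="weibull")
    elif rule == "tukey":
        half = (v.size + 1) // 2
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[v.size - half:]))
    else:
        raise ParameterError(f"unknown quantile rule {rule!r}")
    return med, float(q3 - q1)


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # min(U1, U2), as conventionally reported
    p_value: float  # per requested mode
    U1: float
    U2: float
    p_exact: float | None
    p_normal: float


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u1_obs: float) -> float:
    """Permutation p over all assignments of pooled midranks to sample 1."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    center = n1 * (n - n1) / 2.0
    d_obs = abs(u1_obs - center)
    hits = 0
    for idx in combinations(range(n), n1):
        u1 = ranks[list(idx)].sum() - offset
        if abs(u1 - center) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(
    x,
    y,
    p_mode: Literal["auto", "exact", "normal"] = "auto",
    exact_limit: int = 10,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midranks.

    Returns min(U1, U2) as the reported statistic.  The exact permutation
    p-value is computed when both samples have at most ``exact_limit``
    observations (or ``p_mode='exact'``); the normal approximation applies a
    tie correction to the variance and no continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n1, n2 = xa.size, ya.size
    if n1 == 0 or n2 == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)

    # tie-corrected normal approximation
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        p_normal = 1.0
    else:
        z = (u1 - mu) / sqrt(var)
        p_normal = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0)))))

    p_exact = None
    want_exact = p_mode == "exact" or (p_mode == "auto" and max(n1, n2) <= exact_limit)
    if want_exact:
        p_exact = _exact_two_sided_p(ranks, n1, u1)

    if p_mode == "normal":
        p = p_normal
    elif p_mode == "exact":
        p = p_exact  # type: ignore[assignment]
    else:
        p = p_exact if p_exact is not None else p_normal
    return MannWhitneyResult(U=min(u1, u2), p_value=float(p), U1=u1, U2=u2,
                             p_exact=p_exact, p_normal=p_normal)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    form: str


def _icc_band(value: float) -> str:
    if np.isnan(value):
        return "undefined"
    for threshold, name in ICC_BANDS:
        if value > threshold if name == "excellent" else value >= threshold:
            return name
    return "poor"


def icc(matrix, form: IccForm = "twoway_random_abs", confidence: float = 0.95) -> IccResult:
    """Single-measures intraclass correlation from the ANOVA decomposition.

    ``matrix`` is subjects x raters with no missing cells.  Forms: ``oneway``
    (ICC(1,1)), ``twoway_random_abs`` (ICC(2,1), absolute agreement) and
    ``twoway_mixed_consistency`` (ICC(3,1)).  Confidence bounds follow the
    standard F-distribution constructions.  Zero between-subject variance
    yields NaN with band ``undefined``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InputError("matrix must be at least 2 subjects x 2 raters")
    if np.any(np.isnan(m)):
        raise InputError("matrix must not contain missing cells")
    n, k = m.shape
    alpha = 1.0 - confidence
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))

    if ss_rows <= 1e-300 * max(1.0, ss_total):
        return IccResult(float("nan"), float("nan"), float("nan"), "undefined", form)

    def _from_f(fl: float, fu: float) -> tuple[float, float]:
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)

    if form == "oneway":
        value = (msr - msw) / (msr + (k - 1) * msw)
        if msw == 0.0:
            lo = hi = value
        else:
            fobs = msr / msw
            fl = fobs / f_dist.ppf(1 - alpha / 2, n - 1, n * (k - 1))
            fu = fobs * f_dist.ppf(1 - alpha / 2, n * (k - 1), n - 1)
            lo, hi = _from_f(fl, fu)
    elif form == "twoway_mixed_consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            lo = hi = value
        else:
            fobs = msr / mse
            df2 = (n - 1) * (k - 1)
            fl = fobs / f_dist.ppf(1 - alpha / 2, n - 1, df2)
            fu = fobs * f_dist.ppf(1 - alpha / 2, df2, n - 1)
            lo, hi = _from_f(fl, fu)
    elif form == "twoway_random_abs":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        a = k * value / (n * (1 - value)) if value < 1 else np.inf
        b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
        if np.isfinite(a) and np.isfinite(b) and (a * msc + b * mse) > 0:
            vn = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = f_dist.ppf(1 - alpha / 2, n - 1, vn)
            f2 = f_dist.ppf(1 - alpha / 2, vn, n - 1)
            lo = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = 1.0
    else:
        raise ParameterError(f"unknown ICC form {form!r}")

    value = float(value)
    return IccResult(value, float(min(lo, value)), float(max(hi, value)),
                     _icc_band(value), form)


# -- participant summary tables --------------------------------------------

_T1_REQUIRED = (
    "participant_id", "actual_count", "actual_stride_length",
    "gaitup_count_right", "gaitup_count_left",
    "gaitup_length_right", "gaitup_length_left",
    "insole_count_right", "insole_count_left",
    "approach1_length_right", "approach1_length_left",
    "approach2_length_right", "approach2_length_left",
)
_T4_REQUIRED = (
    "participant_id", "actual_distance",
    "gaitup_distance_right", "gaitup_distance_left",
    "approach1_distance_right", "approach1_distance_left",
    "approach2_distance_right", "approach2_distance_left",
)


@dataclass
class ParticipantTable:
    """Per-participant stride counts, stride lengths and distances."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _T1_REQUIRED if c not in self.data.columns]
        if missing:
            from .errors import FormatError

            raise FormatError(f"participant table missing columns: {missing}")
        num = self.data.drop(columns=["participant_id"]).select_dtypes("number")
        if (num <= 0).any().any():
            raise InputError("all counts, lengths and distances must be positive")
        if self.data["participant_id"].duplicated().any():
            raise InputError("one row per participant required")

    @property
    def has_distances(self) -> bool:
        return all(c in self.data.columns for c in _T4_REQUIRED)

    def length_column(self, method: str, side: str) -> np.ndarray:
        col = f"{method}_length_{side}"
        return self.data[col].to_numpy(dtype=float)

    def count_column(self, method: str, side: str) -> np.ndarray:
        source = "gaitup" if method == "gaitup" else "insole"
        return self.data[f"{source}_count_{side}"].to_numpy(dtype=int)

    def distance_column(self, method: str, side: str) -> np.ndarray:
        return self.data[f"{method}_distance_{side}"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, stride_path, distance_path=None) -> "ParticipantTable":
        """Build from a stride-summary CSV, optionally merged with distances."""
        df = pd.read_csv(stride_path)
        if distance_path is not None:
            df = df.merge(pd.read_csv(distance_path), on="participant_id",
                          validate="one_to_one")
        return cls(df)

    @classmethod
    def bundled(cls) -> "ParticipantTable":
        """The published per-participant summary tables shipped with the package."""
        from importlib.resources import files

        data_dir = files("insolegait") / "data"
        return cls.from_csv(
            str(data_dir / "stride_summary.csv"),
            str(data_dir / "distance_summary.csv"),
        )


@dataclass
class ValidationReport:
    """All derived validation tables for one participant summary."""

    eq1_distances: pd.DataFrame = field(repr=False)
    stride_accuracy: pd.DataFrame = field(repr=False)
    distance_accuracy: pd.DataFrame = field(repr=False)
    medians: pd.DataFrame = field(repr=False)
    u_tests: pd.DataFrame = field(repr=False)
    iccs: pd.DataFrame = field(repr=False)

    def to_text(self) -> str:
        parts = []
        for name in ("eq1_distances", "stride_accuracy", "distance_accuracy",
                     "medians", "u_tests", "iccs"):
            frame = getattr(self, name)
            parts.append(f"== {name} ==\n{frame.to_string(index=False)}")
        return "\n\n".join(parts) + "\n"

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("eq1_distances", "stride_accuracy", "distance_accuracy",
                     "medians", "u_tests", "iccs"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


def build_validation_report(
    table: ParticipantTable,
    icc_form: IccForm = "twoway_random_abs",
    quantile_rule: QuantileRule = "weighted_average",
) -> ValidationReport:
    """Compute all accuracies, medians/IQRs, U tests and ICCs for a table."""
    df = table.data
    pid = df["participant_id"]
    actual_len = df["actual_stride_length"].to_numpy(dtype=float)

    eq1 = pd.DataFrame({"participant_id": pid})
    for method, side in ESTIMATE_COLUMNS:
        lengths = table.length_column(method, side)
        counts = table.count_column(method, side)
        eq1[f"{method}_{side}"] = [
            total_distance(l, int(c)) for l, c in zip(lengths, counts)
        ]

    stride_acc = pd.DataFrame({"participant_id": pid})
    for method, side in ESTIMATE_COLUMNS:
        est = table.length_column(method, side)
        stride_acc[f"{method}_{side}"] = [
            accuracy(a, e).rounded for a, e in zip(actual_len, est)
        ]

    if table.has_distances:
        actual_dist = df["actual_distance"].to_numpy(dtype=float)
        dist_acc = pd.DataFrame({"participant_id": pid})
        for method, side in ESTIMATE_COLUMNS:
            est = table.distance_column(method, side)
            dist_acc[f"{method}_{side}"] = [
                accuracy(a, e).rounded for a, e in zip(actual_dist, est)
            ]
    else:
        actual_dist = None
        dist_acc = pd.DataFrame()

    med_rows = []
    numeric = df.drop(columns=["participant_id"]).select_dtypes("number")
    for col in numeric.columns:
        med, iqr = median_iqr(numeric[col].to_numpy(), rule=quantile_rule)
        med_rows.append({"column": col, "median": med, "iqr": iqr})
    medians = pd.DataFrame(med_rows)

    u_rows = []

    def _add_u(label, x, y):
        res = mann_whitney_u(x, y)
        u_rows.append({
            "comparison": label, "U": res.U,
            "p_exact": res.p_exact, "p_normal": res.p_normal,
        })

    for side in ("right", "left"):
        _add_u(f"stride_approach1_vs_approach2_{side}",
               table.length_column("approach1", side),
               table.length_column("approach2", side))
    if actual_dist is not None:
        for method, side in ESTIMATE_COLUMNS:
            _add_u(f"distance_actual_vs_{method}_{side}",
                   actual_dist, table.distance_column(method, side))

    icc_rows = []

    def _add_icc(label, x, y):
        res = icc(np.column_stack([x, y]), form=icc_form)
        icc_rows.append({
            "comparison": label, "icc": res.icc,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "band": res.band,
        })

    for method, side in ESTIMATE_COLUMNS:
        _add_icc(f"stride_actual_vs_{method}_{side}",
                 actual_len, table.length_column(method, side))
        if actual_dist is not None:
            _add_icc(f"distance_actual_vs_{method}_{side}",
                     actual_dist, table.distance_column(method, side))

    return ValidationReport(
        eq1_distances=eq1,
        stride_accuracy=stride_acc,
        distance_accuracy=dist_acc,
        medians=medians,
        u_tests=pd.DataFrame(u_rows),
        iccs=pd.DataFrame(icc_rows),
    )
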