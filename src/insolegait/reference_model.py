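"""Boundary-constrained cubic reference model of antero-posterior foot position.

One gait cycle is modelled as a cubic position polynomial

    P(t) = c1*t**3 + c2*t**2 + c3*t + c4,   0 <= t <= T,

with the cycle starting at toe-off (t = 0).  Under zero initial position,
zero initial velocity and zero terminal velocity the polynomial is fully
determined by the cycle displacement L and the period T:

    c1 = -2*L/T**3,  c2 = 3*L/T**2,  c3 = c4 = 0.

Velocity and acceleration follow by differentiation; the slope of the
(linear) acceleration, ``6*c1``, is the model's director coefficient used by
the slope-ratio stride estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import InputError, ParameterError

__all__ = [
    "ReferenceModel",
    "analytic_reference_model",
    "fit_reference_polynomial",
    "model_kinematics",
    "model_director_coefficient",
    "read_trajectory_csv",
    "save_model",
    "load_model",
]

#: Default model grid rate (Hz); matches typical mocap capture.
DEFAULT_MODEL_RATE = 100.0


@dataclass(frozen=True)
class ReferenceModel:
    """Cubic position model for one gait cycle starting at toe-off.

    Attributes
    ----------
    c1, c2, c3, c4 : float
        Position polynomial coefficients (m/s^3, m/s^2, m/s, m).
    period_T : float
        Cycle duration in seconds.
    n_samples : int
        Number of samples of the model's native time grid.
    sample_rate : float
        Rate of the native grid (Hz).
    residual_rms : float or None
        RMS of fit residuals when built from data, None for analytic models.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    period_T: float
    n_samples: int
    sample_rate: float
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise ParameterError(f"period_T must be positive, got {self.period_T}")
        if self.n_samples < 4:
            raise ParameterError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")

    # -- evaluation ---------------------------------------------------------

    def position(self, t):
        t = np.asarray(t, dtype=float)
        return ((self.c1 * t + self.c2) * t + self.c3) * t + self.c4

    def velocity(self, t):
        t = np.asarray(t, dtype=float)
        return (3.0 * self.c1 * t + 2.0 * self.c2) * t + self.c3

    def acceleration(self, t):
        t = np.asarray(t, dtype=float)
        return 6.0 * self.c1 * t + 2.0 * self.c2

    @property
    def model_stride_Px(self) -> float:
        """Displacement over one full cycle, P(T)."""
        return float(self.position(self.period_T))

    def time_grid(self, sample_rate: float | None = None) -> np.ndarray:
        """Uniform grid over [0, T] at ``sample_rate`` (native rate if None)."""
        rate = self.sample_rate if sample_rate is None else float(sample_rate)
        if rate <= 0:
            raise ParameterError("sample_rate must be positive")
        n = max(4, int(round(self.period_T * rate)) + 1)
        return np.linspace(0.0, self.period_T, n)

    def swing_grid(
        self, swing_fraction: float = 0.6, sample_rate: float | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, acceleration) over the model swing segment [0, f*T]."""
        if not 0.0 < swing_fraction <= 1.0:
            raise ParameterError("swing_fraction must lie in (0, 1]")
        rate = self.sample_rate if sample_rate is None else float(sample_rate)
        dur = swing_fraction * self.period_T
        n = max(2, int(round(dur * rate)) + 1)
        times = np.linspace(0.0, dur, n)
        return times, self.acceleration(times)


def analytic_reference_model(
    stride_length: float,
    period: float,
    n_samples: int | None = None,
    sample_rate: float = DEFAULT_MODEL_RATE,
) -> ReferenceModel:
    """Build the unique constrained cubic from a stride length and period.

    The returned model satisfies P(0) = 0, V(0) = 0, V(T) = 0 and
    P(T) = ``stride_length`` exactly.

    Parameters
    ----------
    stride_length : float
        Cycle displacement L in metres (>= 0).
    period : float
        Cycle duration T in seconds (> 0).
    n_samples : int, optional
        Native grid size; defaults to ``round(period*sample_rate) + 1``.
    sample_rate : float
        Native grid rate in Hz.
    """
    if period <= 0:
        raise ParameterError(f"period must be positive, got {period}")
    if stride_length < 0:
        raise ParameterError(f"stride_length must be >= 0, got {stride_length}")
    if n_samples is None:
        n_samples = max(4, int(round(period * sample_rate)) + 1)
    c1 = -2.0 * stride_length / period**3
    c2 = 3.0 * stride_length / period**2
    return ReferenceModel(
        c1=c1, c2=c2, c3=0.0, c4=0.0,
        period_T=float(period), n_samples=int(n_samples),
        sample_rate=float(sample_rate),
    )


def fit_reference_polynomial(
    times,
    positions,
    enforce_constraints: bool = True,
) -> ReferenceModel:
    """Least-squares cubic fit of antero-posterior position over one cycle.

    With ``enforce_constraints`` the boundary conditions P(0) = 0, V(0) = 0
    and V(T) = 0 are imposed exactly: the time axis is shifted so the first
    sample is t = 0, the first position is subtracted, and the terminal
    velocity constraint 3*c1*T + 2*c2 = 0 is eliminated analytically, leaving
    a single free coefficient fit in closed form.  Without it a plain
    unconstrained cubic is fit.

    Raises
    ------
    InputError
        Fewer than 4 samples, or non strictly increasing times.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)
    if t.ndim != 1 or p.ndim != 1 or t.size != p.size:
        raise InputError("times and positions must be equal-length 1-D sequences")
    if t.size < 4:
        raise InputError(f"need at least 4 samples, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")

    period = float(t[-1] - t[0])
    n = t.size
    rate = (n - 1) / period

    if enforce_constraints:
        tt = t - t[0]
        pp = p - p[0]
        # P(t) = c1*(t^3 - 1.5*T*t^2) after eliminating c2 = -1.5*c1*T.
        basis = tt**3 - 1.5 * period * tt**2
        denom = float(basis @ basis)
        c1 = float(basis @ pp) / denom if denom > 0 else 0.0
        c2 = -1.5 * c1 * period
        c3 = c4 = 0.0
        resid = pp - c1 * basis
    else:
        c1, c2, c3, c4 = (float(v) for v in np.polyfit(t - t[0], p, 3))
        tt = t - t[0]
        resid = p - (((c1 * tt + c2) * tt + c3) * tt + c4)

    rms = float(np.sqrt(np.mean(resid**2)))
    return ReferenceModel(
        c1=c1, c2=c2, c3=c3, c4=c4,
        period_T=period, n_samples=n, sample_rate=rate,
        residual_rms=rms,
    )


def model_kinematics(model: ReferenceModel, t):
    """Evaluate (position, velocity, acceleration) at time(s) ``t`` in [0, T]."""
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0) or np.any(ta > model.period_T):
        raise ParameterError(
            f"t must lie within [0, {model.period_T}], got {t!r}"
        )
    pos = model.position(ta)
    vel = model.velocity(ta)
    acc = model.acceleration(ta)
    if np.isscalar(t) or ta.ndim == 0:
        return float(pos), float(vel), float(acc)
    return pos, vel, acc


def model_director_coefficient(model: ReferenceModel, absolute: bool = False) -> float:
    """Slope of the model's linear acceleration, 6*c1 (|6*c1| if requested)."""
    d = 6.0 * model.c1
    return abs(d) if absolute else d


# -- serialization ----------------------------------------------------------

def read_trajectory_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a reference trajectory CSV with header ``time_s,position_m``."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    if cols[:2] != ["time_s", "position_m"]:
        from .errors import FormatError

        raise FormatError(
            f"{path}: expected header 'time_s,position_m', got {header!r}"
        )
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return data[:, 0], data[:, 1]


def save_model(model: ReferenceModel, path) -> None:
    """Serialize model parameters to a flat YAML (JSON-compatible) mapping."""
    payload = {
        "c1": model.c1, "c2": model.c2, "c3": model.c3, "c4": model.c4,
        "period_T": model.period_T,
        "n_samples": model.n_samples,
        "sample_rate": model.sample_rate,
        "residual_rms": model.residual_rms,
        "model_stride_Px": model.model_stride_Px,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_model(path) -> ReferenceModel:
    """Load a model written by :func:`save_model` (YAML or JSON)."""
    text = Path(path).read_text()
    try:
        payload = yaml.safe_load(text)
    except yaml.YAMLError:
        payload = json.loads(text)
    return ReferenceModel(
        c1=float(payload["c1"]), c2=float(payload["c2"]),
        c3=float(payload["c3"]), c4=float(payload["c4"]),
        period_T=float(payload["period_T"]),
        n_samples=int(payload["n_samples"]),
        sample_rate=float(payload["sample_rate"]),
        residual_rms=payload.get("residual_rms"),
    )
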