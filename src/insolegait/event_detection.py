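"""Gait-event detection and cycle segmentation for insole recordings.

Toe-off is located from the great-toe pressure channel: each pressure bump is
found with a prominence/separation peak picker, and the event is the first
sample after the bump's maximum where pressure drops below a configurable
fraction of the peak ("end of maximum pressure").  Heel-strike is the largest
local maximum of the antero-posterior acceleration inside each window bounded
by two adjacent toe-offs.  A reference (mocap-like) trajectory is segmented
instead from vertical-displacement minima and antero-posterior plateaus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import ChannelError, InputError

__all__ = [
    "SensorRecording",
    "GaitEventSet",
    "GaitCycle",
    "detect_toe_offs",
    "detect_heel_strikes",
    "segment_cycles",
    "detect_mocap_events",
]

log = logging.getLogger(__name__)

#: Maximum tolerated deviation from a uniform sampling grid, in seconds.
TIME_JITTER_TOL = 1e-6

_PRESSURE_CHANNELS = ("p_heel", "p_toe", "p_met1", "p_met5")


@dataclass
class SensorRecording:
    """Uniform-rate multichannel insole signal.

    ``accel_ap`` is the antero-posterior acceleration (m/s^2); pressure
    channels are in arbitrary sensor units and must be non-negative.
    Optional channels may be ``None``.
    """

    sample_rate: float
    t: np.ndarray
    accel_ap: np.ndarray
    accel_v: np.ndarray | None = None
    accel_ml: np.ndarray | None = None
    p_heel: np.ndarray | None = None
    p_toe: np.ndarray | None = None
    p_met1: np.ndarray | None = None
    p_met5: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InputError(f"sample_rate must be positive, got {self.sample_rate}")
        self.t = np.asarray(self.t, dtype=float)
        self.accel_ap = np.asarray(self.accel_ap, dtype=float)
        n = self.t.size
        for name in ("accel_v", "accel_ml", *_PRESSURE_CHANNELS):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                setattr(self, name, ch)
                if ch.size != n:
                    raise InputError(
                        f"channel {name!r} has {ch.size} samples, expected {n}"
                    )
        if self.accel_ap.size != n:
            raise InputError("accel_ap length does not match time vector")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InputError("time vector must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sample_rate)) > TIME_JITTER_TOL:
                raise InputError(
                    "time vector is not uniform at the declared sample rate "
                    f"(jitter tolerance {TIME_JITTER_TOL} s)"
                )
        for name in _PRESSURE_CHANNELS:
            ch = getattr(self, name)
            if ch is not None and ch.size and float(np.min(ch)) < 0:
                raise InputError(f"pressure channel {name!r} has negative values")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class GaitEventSet:
    """Detected toe-off and heel-strike sample indices."""

    toe_off_idx: np.ndarray
    heel_strike_idx: np.ndarray

    def __post_init__(self) -> None:
        self.toe_off_idx = np.asarray(self.toe_off_idx, dtype=int)
        self.heel_strike_idx = np.asarray(self.heel_strike_idx, dtype=int)
        for name, idx in (("toe_off_idx", self.toe_off_idx),
                          ("heel_strike_idx", self.heel_strike_idx)):
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise InputError(f"{name} must be strictly increasing")


@dataclass
class GaitCycle:
    """One gait cycle between two adjacent toe-offs.

    ``swing_accel`` holds the antero-posterior acceleration over the swing
    window [start_idx, heel_strike_idx] inclusive.
    """

    start_idx: int
    end_idx: int
    heel_strike_idx: int
    swing_accel: np.ndarray
    duration: float
    sample_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.start_idx < self.heel_strike_idx < self.end_idx:
            raise InputError(
                "cycle must satisfy start < heel_strike < end, got "
                f"{self.start_idx}, {self.heel_strike_idx}, {self.end_idx}"
            )
        self.swing_accel = np.asarray(self.swing_accel, dtype=float)
        if self.swing_accel.size == 0:
            raise InputError("swing_accel must be non-empty")
        if self.duration <= 0:
            raise InputError("cycle duration must be positive")


def detect_toe_offs(
    recording: SensorRecording,
    min_separation: float = 0.4,
    prominence_frac: float = 0.2,
    drop_frac: float = 0.5,
) -> np.ndarray:
    """Toe-off sample indices from the great-toe pressure channel.

    Peaks of ``p_toe`` with the given minimum separation (seconds) and
    prominence (fraction of the channel's range) mark maximum-pressure
    episodes; each event is the first subsequent sample whose pressure falls
    below ``drop_frac`` of the peak value.

    Returns an increasing, deduplicated index array.  A flat channel yields
    an empty result with a warning.
    """
    if recording.p_toe is None:
        raise ChannelError("p_toe")
    if min_separation <= 0:
        raise InputError("min_separation must be positive")
    p = recording.p_toe
    rng = float(np.ptp(p)) if p.size else 0.0
    if rng == 0.0:
        warnings.warn("great-toe pressure channel is flat; no toe-offs detected",
                      stacklevel=2)
        return np.empty(0, dtype=int)
    distance = max(1, int(round(min_separation * recording.sample_rate)))
    peaks, _ = find_peaks(p, distance=distance, prominence=prominence_frac * rng)
    events: list[int] = []
    for pk in peaks:
        below = np.nonzero(p[pk + 1:] < drop_frac * p[pk])[0]
        if below.size == 0:
            log.debug("toe-pressure peak at %d never drops below threshold; skipped", pk)
            continue
        events.append(int(pk + 1 + below[0]))
    return np.unique(np.asarray(events, dtype=int))


def detect_heel_strikes(recording: SensorRecording, toe_offs) -> np.ndarray:
    """Heel-strike indices: largest AP-acceleration local maximum per window.

    Each window spans two adjacent toe-offs (exclusive of its endpoints).  A
    window that contains no local maximum is skipped and logged.  Requires at
    least two toe-offs.
    """
    toe_offs = np.asarray(toe_offs, dtype=int)
    if toe_offs.size < 2:
        raise InputError("need at least 2 toe-off events to bound a window")
    a = recording.accel_ap
    # islocalmax-style mask; ties resolved to the earliest sample of a plateau
    mask = np.zeros(a.size, dtype=bool)
    if a.size >= 3:
        interior = (a[1:-1] > a[:-2]) & (a[1:-1] >= a[2:])
        mask[1:-1] = interior
    out: list[int] = []
    for lo, hi in zip(toe_offs[:-1], toe_offs[1:]):
        sl = slice(lo + 1, hi)
        cand = np.nonzero(mask[sl])[0]
        if cand.size == 0:
            log.warning("no local AP-acceleration maximum in window (%d, %d); skipped",
                        lo, hi)
            continue
        vals = a[sl][cand]
        out.append(int(lo + 1 + cand[np.argmax(vals)]))
    return np.asarray(out, dtype=int)


def segment_cycles(recording: SensorRecording, events: GaitEventSet) -> list[GaitCycle]:
    """One :class:`GaitCycle` per adjacent toe-off pair containing a heel-strike.

    Windows are half-open ``[toe_off, next_toe_off)``; windows without a
    heel-strike are dropped.  Incomplete leading/trailing partials never form
    cycles because a cycle needs both bounding toe-offs.
    """
    tos = events.toe_off_idx
    hss = events.heel_strike_idx
    cycles: list[GaitCycle] = []
    if tos.size < 2:
        return cycles
    for lo, hi in zip(tos[:-1], tos[1:]):
        inside = hss[(hss > lo) & (hss < hi)]
        if inside.size == 0:
            log.info("window (%d, %d) has no heel-strike; cycle dropped", lo, hi)
            continue
        hs = int(inside[0])
        cycles.append(
            GaitCycle(
                start_idx=int(lo),
                end_idx=int(hi),
                heel_strike_idx=hs,
                swing_accel=recording.accel_ap[lo: hs + 1],
                duration=(hi - lo) / recording.sample_rate,
                sample_rate=recording.sample_rate,
            )
        )
    log.info("segmented %d gait cycles from %d toe-offs", len(cycles), tos.size)
    return cycles


def detect_mocap_events(
    times,
    displacement_v,
    displacement_ap,
    search_window: tuple[float, float] = (0.1, 0.8),
    plateau_velocity: float = 0.02,
    plateau_min_samples: int = 3,
) -> GaitEventSet:
    """Segment a reference trajectory into toe-off / heel-strike events.

    Starting from the first sample (assumed to be a toe-off), each next
    toe-off is the minimum of the vertical displacement within
    ``search_window`` seconds after the previous one (ties -> earliest
    sample).  Within each toe-off pair, the heel-strike is the first sample
    where the antero-posterior displacement reaches its plateau:
    |d(AP)/dt| < ``plateau_velocity`` for at least ``plateau_min_samples``
    consecutive samples.  A strictly rising AP displacement yields no
    heel-strike for that window (warned).
    """
    t = np.asarray(times, dtype=float)
    dv = np.asarray(displacement_v, dtype=float)
    dap = np.asarray(displacement_ap, dtype=float)
    if t.size != dv.size or t.size != dap.size:
        raise InputError("times and displacement channels must share one length")
    if t.size < 3:
        raise InputError("trajectory too short to segment")

    toe_offs = [0]
    w0, w1 = search_window
    while True:
        t_last = t[toe_offs[-1]]
        # only complete windows are searched; a window truncated by the end
        # of the data would report its own edge as a spurious minimum
        if t_last + w1 > t[-1] + 1e-9:
            break
        sel = np.nonzero((t >= t_last + w0) & (t <= t_last + w1))[0]
        if sel.size == 0:
            break
        nxt = int(sel[np.argmin(dv[sel])])
        if nxt <= toe_offs[-1]:
            break
        toe_offs.append(nxt)

    vel = np.gradient(dap, t)
    slow = np.abs(vel) < plateau_velocity
    heel_strikes: list[int] = []
    for lo, hi in zip(toe_offs[:-1], toe_offs[1:]):
        found = None
        run = 0
        for i in range(lo + 1, hi):
            run = run + 1 if slow[i] else 0
            if run >= plateau_min_samples:
                found = i - plateau_min_samples + 1
                break
        if found is None:
            warnings.warn(
                f"no AP-displacement plateau between samples {lo} and {hi}; "
                "heel-strike skipped", stacklevel=2,
            )
            continue
        heel_strikes.append(int(found))
    return GaitEventSet(
        toe_off_idx=np.asarray(toe_offs, dtype=int),
        heel_strike_idx=np.asarray(heel_strikes, dtype=int),
    )
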