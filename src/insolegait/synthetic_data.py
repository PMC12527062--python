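"""Synthetic insole recordings and mocap-like trajectories with ground truth.

The generator lays out a stride timeline (toe-off -> swing -> heel-strike ->
stance -> next toe-off) and synthesizes:

* antero-posterior acceleration: during swing, the negated linear
  acceleration of the constrained cubic for that stride's (L, T) — a ramp
  that starts deep negative at toe-off, rises through the swing, and peaks
  exactly at heel-strike; near zero during stance;
* great-toe pressure: a rise-then-plateau pulse that is at maximum through
  late stance and drops to zero exactly at toe-off ("end of maximum
  pressure");
* heel pressure: a raised-cosine bump starting at heel-strike.

Every sample index of every true event is recorded in a ground-truth
annotation so detectors and estimators can be scored exactly.  All noise is
drawn from a single seeded generator; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .event_detection import SensorRecording

__all__ = ["GaitProfile", "GroundTruth", "generate_recording",
           "generate_mocap_trajectory"]

PRESSURE_AMPLITUDE = 100.0  # arbitrary sensor units


@dataclass(frozen=True)
class GaitProfile:
    """Specification of a synthetic walk: per-stride lengths and timings."""

    n_strides: int
    stride_lengths: np.ndarray
    cycle_durations: np.ndarray
    swing_fraction: float = 0.6
    sample_rate: float = 40.0
    noise_sd_accel: float = 0.0
    noise_sd_pressure: float = 0.0  # fraction of the pressure amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stride_lengths",
                           np.asarray(self.stride_lengths, dtype=float))
        object.__setattr__(self, "cycle_durations",
                           np.asarray(self.cycle_durations, dtype=float))
        if self.n_strides < 0:
            raise ParameterError("n_strides must be >= 0")
        if (self.stride_lengths.size != self.n_strides
                or self.cycle_durations.size != self.n_strides):
            raise ParameterError(
                "stride_lengths and cycle_durations must have n_strides entries")
        if not 0.0 < self.swing_fraction < 1.0:
            raise ParameterError("swing_fraction must lie in (0, 1)")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.noise_sd_accel < 0 or self.noise_sd_pressure < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.n_strides and (np.any(self.stride_lengths < 0)
                               or np.any(self.cycle_durations <= 0)):
            raise ParameterError("stride lengths must be >= 0, durations > 0")

    @classmethod
    def constant(cls, n_strides: int, stride_length: float = 1.5,
                 period: float = 1.0, **kwargs) -> "GaitProfile":
        """Profile with identical stride length and period for every stride."""
        return cls(
            n_strides=n_strides,
            stride_lengths=np.full(n_strides, stride_length),
            cycle_durations=np.full(n_strides, period),
            **kwargs,
        )


@dataclass(frozen=True)
class GroundTruth:
    """True event indices and stride lengths for one synthetic recording."""

    toe_off_idx: np.ndarray
    heel_strike_idx: np.ndarray
    true_stride_lengths: np.ndarray
    true_total_distance: float
    seed: int
    true_cycle_durations: np.ndarray = field(default_factory=lambda: np.empty(0))


def _raised_cosine_rise(n: int) -> np.ndarray:
    """Smooth 0 -> 1 ramp over n samples."""
    x = np.linspace(0.0, 1.0, n)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def generate_recording(profile: GaitProfile) -> tuple[SensorRecording, GroundTruth]:
    """Synthesize an insole recording and its exact ground truth."""
    fs = profile.sample_rate
    lead = int(round(0.5 * fs))  # room before the first toe-off
    tail = int(round(0.5 * fs))

    if profile.n_strides == 0:
        empty = np.empty(0)
        rec = SensorRecording(
            sample_rate=fs, t=empty, accel_ap=empty,
            accel_v=empty.copy(), accel_ml=empty.copy(),
            p_heel=empty.copy(), p_toe=empty.copy(),
            p_met1=empty.copy(), p_met5=empty.copy(),
        )
        truth = GroundTruth(
            toe_off_idx=np.empty(0, dtype=int),
            heel_strike_idx=np.empty(0, dtype=int),
            true_stride_lengths=np.empty(0),
            true_total_distance=0.0, seed=profile.seed,
        )
        return rec, truth

    toe_offs = [lead]
    heel_strikes = []
    for dur in profile.cycle_durations:
        start = toe_offs[-1]
        heel_strikes.append(start + int(round(profile.swing_fraction * dur * fs)))
        toe_offs.append(start + int(round(dur * fs)))
    n = toe_offs[-1] + tail

    accel_ap = np.zeros(n)
    p_toe = np.zeros(n)
    p_heel = np.zeros(n)

    for i, (length, dur) in enumerate(zip(profile.stride_lengths,
                                          profile.cycle_durations)):
        to, hs = toe_offs[i], heel_strikes[i]
        c1 = -2.0 * length / dur**3
        c2 = 3.0 * length / dur**2
        tau = (np.arange(to, hs + 1) - to) / fs
        # negated model acceleration: rises from -6L/T^2 to its peak at
        # heel-strike, matching the measured-signal morphology
        accel_ap[to: hs + 1] = -(6.0 * c1 * tau + 2.0 * c2)

    rise_n = max(2, int(round(0.1 * fs)))
    for i, to in enumerate(toe_offs):
        dur = profile.cycle_durations[min(i, profile.n_strides - 1)]
        stance_n = int(round((1.0 - profile.swing_fraction) * dur * fs))
        bump_n = max(rise_n + 1, int(round(0.75 * stance_n)))
        start = max(0, to - bump_n)
        plateau_start = start + rise_n
        p_toe[start:plateau_start] = PRESSURE_AMPLITUDE * _raised_cosine_rise(rise_n)
        p_toe[plateau_start:to] = PRESSURE_AMPLITUDE  # pressure max ends at toe-off

    bump_len = max(3, int(round(0.3 * fs)))
    heel_bump = PRESSURE_AMPLITUDE * np.sin(
        np.pi * np.linspace(0.0, 1.0, bump_len)) ** 2
    for hs in heel_strikes:
        stop = min(n, hs + bump_len)
        p_heel[hs:stop] = np.maximum(p_heel[hs:stop], heel_bump[: stop - hs])

    rng = np.random.default_rng(profile.seed)
    accel_v = np.zeros(n)
    accel_ml = np.zeros(n)
    if profile.noise_sd_accel > 0:
        accel_ap = accel_ap + rng.normal(0.0, profile.noise_sd_accel, n)
        accel_v = accel_v + rng.normal(0.0, profile.noise_sd_accel, n)
        accel_ml = accel_ml + rng.normal(0.0, profile.noise_sd_accel, n)
    p_met1 = 0.6 * p_toe
    p_met5 = 0.4 * p_heel
    if profile.noise_sd_pressure > 0:
        sd = profile.noise_sd_pressure * PRESSURE_AMPLITUDE
        for arr in (p_toe, p_heel, p_met1, p_met5):
            arr += rng.normal(0.0, sd, n)
            np.clip(arr, 0.0, None, out=arr)

    rec = SensorRecording(
        sample_rate=fs,
        t=np.arange(n) / fs,
        accel_ap=accel_ap,
        accel_v=accel_v,
        accel_ml=accel_ml,
        p_heel=p_heel,
        p_toe=p_toe,
        p_met1=p_met1,
        p_met5=p_met5,
    )
    truth = GroundTruth(
        toe_off_idx=np.asarray(toe_offs, dtype=int),
        heel_strike_idx=np.asarray(heel_strikes, dtype=int),
        true_stride_lengths=profile.stride_lengths.copy(),
        true_total_distance=float(np.sum(profile.stride_lengths)),
        seed=profile.seed,
        true_cycle_durations=profile.cycle_durations.copy(),
    )
    return rec, truth


def generate_mocap_trajectory(
    stride_length: float,
    period: float,
    n_cycles: int,
    noise_sd: float = 0.0,
    sample_rate: float = 100.0,
    seed: int = 0,
    swing_fraction: float = 0.6,
    arch_height: float = 0.08,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Mocap-like foot trajectory: cumulative cubic advances plus vertical arches.

    Per cycle the antero-posterior displacement follows the constrained cubic
    over the swing segment (duration ``swing_fraction * period``) and then
    holds a plateau until the next toe-off; the vertical displacement is a
    smooth arch that is zero exactly at each toe-off.  Returns
    ``(times, displacement_ap, displacement_v, truth)``.
    """
    if stride_length < 0 or period <= 0 or n_cycles < 0:
        raise ParameterError("need stride_length >= 0, period > 0, n_cycles >= 0")
    if sample_rate <= 0 or noise_sd < 0 or not 0 < swing_fraction < 1:
        raise ParameterError("invalid sampling/noise/swing parameters")

    per_cycle = int(round(period * sample_rate))
    # stance tail past the final toe-off so event detectors can search a
    # complete window around it
    tail = int(round(0.3 * sample_rate))
    n = n_cycles * per_cycle + tail + 1
    times = np.arange(n) / sample_rate
    ap = np.zeros(n)
    vert = np.zeros(n)

    swing_dur = swing_fraction * period
    c1 = -2.0 * stride_length / swing_dur**3
    c2 = 3.0 * stride_length / swing_dur**2
    toe_offs = [k * per_cycle for k in range(n_cycles + 1)]
    heel_strikes = []
    for k in range(n_cycles):
        to = toe_offs[k]
        nxt = toe_offs[k + 1]
        hs = to + int(round(swing_dur * sample_rate))
        heel_strikes.append(hs)
        tau = times[to: hs + 1] - times[to]
        ap[to: hs + 1] = k * stride_length + (c1 * tau + c2) * tau**2
        ap[hs + 1: nxt + 1] = (k + 1) * stride_length
        phase = (times[to: nxt + 1] - times[to]) / period
        vert[to: nxt + 1] = arch_height * np.sin(np.pi * phase) ** 2

    if n_cycles:
        last = toe_offs[-1]
        ap[last:] = n_cycles * stride_length
        phase = (times[last:] - times[last]) / period
        vert[last:] = arch_height * np.sin(np.pi * phase) ** 2

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ap = ap + rng.normal(0.0, noise_sd, n)
        vert = vert + rng.normal(0.0, noise_sd, n)

    truth = GroundTruth(
        toe_off_idx=np.asarray(toe_offs, dtype=int),
        heel_strike_idx=np.asarray(heel_strikes, dtype=int),
        true_stride_lengths=np.full(n_cycles, stride_length),
        true_total_distance=float(n_cycles * stride_length),
        seed=seed,
        true_cycle_durations=np.full(n_cycles, period),
    )
    return times, ap, vert, truth
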