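import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import insolegait.stride_estimation as se
from insolegait import (DegenerateModelError, GaitCycle, InputError,
                        ParameterError, ReferenceModel, analytic_reference_model,
                        approach1_stride_length, approach2_stride_length,
                        dtw_distance, scaling_coefficient, swing_slope,
                        total_distance)
from oracles import dtw_bruteforce, ols_slope


def _cycle_from_swing(swing, duration=1.0, fs=40.0):
    swing = np.asarray(swing, dtype=float)
    n = swing.size
    return GaitCycle(start_idx=0, end_idx=n + 10, heel_strike_idx=n - 1,
                     swing_accel=swing, duration=duration, sample_rate=fs)


def _model_grid_cycles(model, scales, fs=40.0, swing_fraction=0.6):
    """Cycles whose swing acceleration is scale * model acceleration on the grid."""
    _, accel = model.swing_grid(swing_fraction, sample_rate=fs)
    return [_cycle_from_swing(k * accel, duration=model.period_T, fs=fs)
            for k in scales]


class TestSwingSlope:
    def test_exact_line(self):
        t = np.arange(50) / 40.0
        assert swing_slope(2.0 * t + 1.0, sample_rate=40.0) == pytest.approx(2.0)

    def test_constant_signal(self):
        assert swing_slope(np.full(30, 4.2), sample_rate=40.0) == 0.0

    def test_noisy_line_within_5pct(self, rng):
        t = np.arange(40) / 40.0
        y = 3.0 * t + rng.normal(0.0, 0.01, 40)
        assert swing_slope(y, sample_rate=40.0) == pytest.approx(3.0, rel=0.05)

    def test_matches_closed_form_oracle(self, rng):
        t = np.arange(25) / 40.0
        y = rng.normal(size=25)
        assert swing_slope(y, times=t) == pytest.approx(
            ols_slope(list(t), list(y)))

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            swing_slope([1.0], sample_rate=40.0)

    def test_zero_time_variance(self):
        with pytest.raises(InputError):
            swing_slope([1.0, 2.0], times=[0.5, 0.5])

    def test_centering_does_not_change_slope(self, rng):
        y = rng.normal(size=30) + 5.0
        a = swing_slope(y, sample_rate=40.0, center=True)
        b = swing_slope(y, sample_rate=40.0, center=False)
        assert a == pytest.approx(b)


class TestApproach1:
    def test_identity_cycles_give_R1(self, model_15_10):
        cycles = _model_grid_cycles(model_15_10, [1.0, 1.0, 1.0])
        est = approach1_stride_length(cycles, model_15_10)
        assert est.mean_R == pytest.approx(1.0, rel=1e-9)
        assert est.stride_length_L == pytest.approx(model_15_10.model_stride_Px,
                                                    rel=1e-9)

    def test_amplitude_scale_recovered(self, model_15_10):
        cycles = _model_grid_cycles(model_15_10, [1.3])
        est = approach1_stride_length(cycles, model_15_10)
        assert est.stride_length_L == pytest.approx(
            1.3 * model_15_10.model_stride_Px, rel=1e-9)

    def test_mean_of_ratios(self, model_15_10):
        cycles = _model_grid_cycles(model_15_10, [0.9, 1.1])
        est = approach1_stride_length(cycles, model_15_10)
        assert est.mean_R == pytest.approx(1.0, rel=1e-9)
        assert est.stride_length_L == pytest.approx(1.5, rel=1e-9)

    def test_offset_invariance(self, model_15_10):
        base = _model_grid_cycles(model_15_10, [1.0])
        shifted = [_cycle_from_swing(base[0].swing_accel + 7.3,
                                     duration=model_15_10.period_T)]
        a = approach1_stride_length(base, model_15_10)
        b = approach1_stride_length(shifted, model_15_10)
        assert a.stride_length_L == pytest.approx(b.stride_length_L, rel=1e-12)

    def test_amplitude_equivariance(self, model_15_10):
        a = approach1_stride_length(_model_grid_cycles(model_15_10, [1.0]),
                                    model_15_10)
        b = approach1_stride_length(_model_grid_cycles(model_15_10, [2.0]),
                                    model_15_10)
        assert b.stride_length_L == pytest.approx(2 * a.stride_length_L, rel=1e-12)

    def test_degenerate_model_rejected(self):
        model = analytic_reference_model(0.0, 1.0)
        cycles = [_cycle_from_swing(np.arange(10.0))]
        with pytest.raises(DegenerateModelError):
            approach1_stride_length(cycles, model)

    def test_zero_slope_cycle_warns_and_contributes_zero(self, model_15_10):
        cycles = [_cycle_from_swing(np.zeros(20), duration=1.0)]
        with pytest.warns(UserWarning):
            est = approach1_stride_length(cycles, model_15_10)
        assert est.per_cycle_values.tolist() == [0.0]
        assert est.stride_length_L == 0.0

    def test_empty_cycles_rejected(self, model_15_10):
        with pytest.raises(InputError):
            approach1_stride_length([], model_15_10)

    def test_inverse_ratio_convention(self, model_15_10):
        cycles = _model_grid_cycles(model_15_10, [2.0])
        est = approach1_stride_length(cycles, model_15_10,
                                      ratio_convention="model_over_insole")
        assert est.mean_R == pytest.approx(0.5, rel=1e-9)

    def test_estimate_invariant(self, model_15_10):
        # L = Px * mean(R) is exact by construction
        cycles = _model_grid_cycles(model_15_10, [0.8, 1.0, 1.4])
        est = approach1_stride_length(cycles, model_15_10)
        assert est.stride_length_L == pytest.approx(
            est.model_stride_Px * est.mean_R, rel=1e-12)

    def test_noise_free_recovery_within_2pct(self, clean_walk, clean_cycles):
        _, truth = clean_walk
        period = float(np.mean([c.duration for c in clean_cycles]))
        model = analytic_reference_model(1.5, period)
        est = approach1_stride_length(clean_cycles, model)
        true_L = float(np.mean(truth.true_stride_lengths))
        assert abs(est.stride_length_L - true_L) / true_L <= 0.02


class TestDtw:
    def test_identical_sequences(self):
        assert dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_small_example(self):
        # brute-force enumeration over the 3x3 grid gives 2
        assert dtw_distance([1, 2, 3], [2, 3, 4]) == 2.0

    def test_single_cell(self):
        assert dtw_distance([0.0], [5.0]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            dtw_distance([], [1.0])

    def test_symmetry_and_identity(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(1, 7))
            b = rng.normal(size=rng.integers(1, 7))
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))
        a = rng.normal(size=5)
        assert dtw_distance(a, a) == 0.0

    def test_never_exceeds_diagonal_then_edge_path(self, rng):
        for _ in range(20):
            a = rng.normal(size=6)
            b = rng.normal(size=4)
            k = min(a.size, b.size)
            path_cost = float(np.sum(np.abs(a[:k] - b[:k])))
            path_cost += float(np.sum(np.abs(a[k:] - b[-1])))
            path_cost += float(np.sum(np.abs(b[k:] - a[-1])))
            assert dtw_distance(a, b) <= path_cost + 1e-12

    def test_matches_bruteforce_suite(self, rng):
        for _ in range(40):
            a = rng.integers(-5, 6, size=rng.integers(1, 7)).astype(float)
            b = rng.integers(-5, 6, size=rng.integers(1, 7)).astype(float)
            assert dtw_distance(a, b) == pytest.approx(
                dtw_bruteforce(a.tolist(), b.tolist()))

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.lists(st.floats(-10, 10), min_size=1, max_size=5),
        b=st.lists(st.floats(-10, 10), min_size=1, max_size=5),
    )
    def test_bruteforce_property(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b))


class TestScalingCoefficient:
    def test_mean_abs_example(self):
        assert scaling_coefficient([2.0, -2.0, 2.0, -2.0]) == pytest.approx(0.5)

    def test_single_sample(self):
        assert scaling_coefficient([1.0]) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            scaling_coefficient([0.0, 0.0, 0.0])

    def test_alternative_norms(self):
        a = [3.0, -4.0]
        assert scaling_coefficient(a, norm="euclidean") == pytest.approx(0.2)
        assert scaling_coefficient(a, norm="max_abs") == pytest.approx(0.25)

    def test_unknown_norm(self):
        with pytest.raises(ParameterError):
            scaling_coefficient([1.0], norm="rms")


class TestApproach2:
    def test_worked_example(self):
        # model swing grid [1, 2], insole swing [2, 3]:
        # d = 2, S = 1/2.5 = 0.4, E = 0.8, L = 0.8 * Px
        model = ReferenceModel(c1=1.0 / 3.6, c2=0.5, c3=0.0, c4=0.0,
                               period_T=1.0, n_samples=4, sample_rate=5 / 3)
        cycle = _cycle_from_swing([2.0, 3.0], duration=1.0, fs=5 / 3)
        est = approach2_stride_length([cycle], model, sample_rate=5 / 3)
        assert est.per_cycle_values.tolist() == [2.0]
        assert est.scaling_S == pytest.approx(0.4)
        assert est.E == pytest.approx(0.8)
        assert est.stride_length_L == pytest.approx(0.8 * model.model_stride_Px)

    def test_identity_degenerates_to_zero(self, model_15_10):
        cycles = _model_grid_cycles(model_15_10, [1.0, 1.0])
        with pytest.warns(UserWarning):
            est = approach2_stride_length(cycles, model_15_10)
        assert est.per_cycle_values.tolist() == [0.0, 0.0]
        assert est.E == 0.0
        assert est.stride_length_L == 0.0

    def test_doubling_costs_doubles_E_and_L(self, model_15_10, monkeypatch):
        cycles = _model_grid_cycles(model_15_10, [1.0, 1.0, 1.0])
        fake = iter([1.0, 2.0, 3.0, 2.0, 4.0, 6.0])
        monkeypatch.setattr(se, "dtw_distance", lambda a, b: next(fake))
        one = se.approach2_stride_length(cycles, model_15_10)
        two = se.approach2_stride_length(cycles, model_15_10)
        assert two.E == pytest.approx(2 * one.E)
        assert two.stride_length_L == pytest.approx(2 * one.stride_length_L)

    def test_monotone_in_each_cost(self, model_15_10, monkeypatch):
        cycles = _model_grid_cycles(model_15_10, [1.0, 1.0, 1.0])
        costs = iter([1.0, 2.0, 3.0, 1.0, 2.0, 4.0])
        monkeypatch.setattr(se, "dtw_distance", lambda a, b: next(costs))
        low = se.approach2_stride_length(cycles, model_15_10)
        high = se.approach2_stride_length(cycles, model_15_10)
        assert high.stride_length_L > low.stride_length_L

    def test_all_zero_swing_rejected(self, model_15_10):
        cycles = [_cycle_from_swing(np.zeros(20))]
        with pytest.raises(InputError):
            approach2_stride_length(cycles, model_15_10)

    def test_empty_cycles_rejected(self, model_15_10):
        with pytest.raises(InputError):
            approach2_stride_length([], model_15_10)

    def test_estimate_invariant(self, model_15_10):
        cycles = _model_grid_cycles(model_15_10, [1.2, 0.7])
        est = approach2_stride_length(cycles, model_15_10)
        assert est.stride_length_L == pytest.approx(
            est.model_stride_Px * est.E, rel=1e-12)
        assert est.E == pytest.approx(
            float(np.mean(est.per_cycle_values)) * est.scaling_S, rel=1e-12)


class TestTotalDistance:
    def test_published_examples(self):
        assert total_distance(1.681, 367) == 616.93
        assert total_distance(1.800, 413) == 743.40

    def test_half_up_rounding(self):
        assert total_distance(1.535, 363) == 557.21
        assert total_distance(1.525, 413) == 629.83

    def test_zero_length(self):
        assert total_distance(0.0, 400) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            total_distance(-1.0, 10)
        with pytest.raises(ParameterError):
            total_distance(1.0, -1)

    def test_non_integer_count_rejected(self):
        with pytest.raises(ParameterError):
            total_distance(1.0, 3.5)
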