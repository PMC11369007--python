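import numpy as np
import pytest

from petdisplace import (
    AutosamplerSeries,
    BloodSampleSet,
    C11_HALF_LIFE_MIN,
    InputFunction,
    ParentFractionModel,
    build_input_function,
    calibrate_autosampler,
    decay_correct,
    decay_uncorrect,
    fit_parent_fraction,
)
from petdisplace.synthetic import InputFunctionParams, generate_input_function


class TestDecayCorrection:
    def test_one_half_life_doubles(self):
        assert decay_correct(10.0, C11_HALF_LIFE_MIN) == pytest.approx(20.0)

    def test_time_zero_is_identity(self):
        assert decay_correct(7.3, 0.0) == 7.3

    def test_round_trip(self):
        t = np.linspace(0, 120, 13)
        a = np.linspace(5, 50, 13)
        assert np.allclose(decay_uncorrect(decay_correct(a, t), t), a, rtol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(1.0, -0.1)


class TestAutosamplerCalibration:
    def _manual(self, times, wb):
        return BloodSampleSet(times, wb, 0.8 * np.asarray(wb))

    def test_exactly_proportional_counts_recover_factor(self):
        t_s = np.arange(0.0, 601.0)
        wb_true = np.full(t_s.size, 50.0)
        counts = decay_uncorrect(wb_true, t_s / 60.0) / 2.5 + 10.0
        auto = AutosamplerSeries(t_s, counts, background=10.0)
        manual = self._manual(np.array([2.0, 5.0, 9.0]), wb_true[[120, 300, 540]])
        cal = calibrate_autosampler(auto, manual)
        assert cal.factor == pytest.approx(2.5, rel=1e-9)
        assert cal.residual_ss == pytest.approx(0.0, abs=1e-12)
        assert not cal.degenerate

    def test_zero_counts_flagged_degenerate(self):
        t_s = np.arange(0.0, 601.0)
        auto = AutosamplerSeries(t_s, np.zeros_like(t_s), background=0.0)
        manual = self._manual(np.array([2.0, 5.0]), np.array([10.0, 8.0]))
        cal = calibrate_autosampler(auto, manual)
        assert cal.degenerate
        assert np.all(cal.whole_blood[: t_s.size] == 0.0)

    def test_noisy_counts_recover_factor_within_2_percent(self):
        rng = np.random.default_rng(42)
        t_s = np.arange(0.0, 601.0)
        wb_true = 60.0 * np.exp(-t_s / 500.0)
        counts = decay_uncorrect(wb_true, t_s / 60.0) / 2.5 + 20.0
        counts = counts + rng.normal(0, 0.5, counts.size)
        auto = AutosamplerSeries(t_s, counts, background=20.0)
        times = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        manual = self._manual(times, np.interp(times * 60, t_s, wb_true))
        cal = calibrate_autosampler(auto, manual)
        assert cal.factor == pytest.approx(2.5, rel=0.02)

    def test_no_overlap_instructs_manual_only(self):
        t_s = np.arange(0.0, 601.0)
        auto = AutosamplerSeries(t_s, np.ones_like(t_s), background=0.0)
        manual = self._manual(np.array([20.0, 40.0]), np.array([5.0, 3.0]))
        with pytest.raises(ValueError, match="manual-only"):
            calibrate_autosampler(auto, manual)

    def test_merge_appends_manual_samples_after_window(self):
        t_s = np.arange(0.0, 601.0)
        wb_true = 50.0 * np.exp(-t_s / 400.0)
        counts = decay_uncorrect(wb_true, t_s / 60.0) / 2.0
        auto = AutosamplerSeries(t_s, counts, background=0.0)
        manual = self._manual(
            np.array([2.0, 8.0, 30.0, 60.0]), np.array([45.0, 44.0, 20.0, 10.0])
        )
        cal = calibrate_autosampler(auto, manual)
        assert cal.time_min[-2:] == pytest.approx([30.0, 60.0])
        assert cal.whole_blood[-2:] == pytest.approx([20.0, 10.0])


class TestParentFraction:
    def test_model_is_one_at_time_zero(self):
        assert ParentFractionModel(0.2, 30.0, 2.0)(0.0) == 1.0

    def test_all_parent_gives_unit_model(self):
        s = BloodSampleSet(
            np.array([5.0, 30.0, 60.0]),
            np.ones(3), np.ones(3), np.ones(3),
        )
        model = fit_parent_fraction(s)
        t = np.linspace(0, 120, 50)
        assert np.allclose(model(t), 1.0, atol=1e-6)

    def test_parameter_recovery_within_5_percent(self):
        truth = ParentFractionModel(b=0.2, c=30.0, n=2.0)
        t = np.array([2.5, 5, 10, 25, 40, 55, 70, 90, 105, 120], float)
        s = BloodSampleSet(t, np.ones(t.size), np.ones(t.size), truth(t))
        model = fit_parent_fraction(s)
        assert model.b == pytest.approx(0.2, rel=0.05)
        assert model.c == pytest.approx(30.0, rel=0.05)
        assert model.n == pytest.approx(2.0, rel=0.05)

    def test_fewer_than_three_samples_rejected(self):
        s = BloodSampleSet(np.array([5.0, 30.0]), np.ones(2), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            fit_parent_fraction(s)

    def test_model_bounded_and_nonincreasing(self):
        model = ParentFractionModel(0.1, 20.0, 3.0)
        t = np.linspace(0, 300, 400)
        pf = model(t)
        assert np.all((pf >= 0) & (pf <= 1))
        assert np.all(np.diff(pf) <= 1e-12)


class TestInputFunction:
    def test_evaluation_at_sample_times_returns_sample_values(self):
        t = np.array([0.0, 1.0, 5.0, 20.0, 60.0])
        cp = np.array([0.0, 40.0, 25.0, 10.0, 4.0])
        wb = cp * 0.8
        f = InputFunction(t, cp, wb)
        assert np.allclose(f.plasma_parent(t), cp)
        assert np.allclose(f.whole_blood(t), wb)

    def test_exponential_tail_beyond_last_sample(self):
        t = np.array([0.0, 40.0, 50.0, 60.0])
        cp = np.array([0.0, 16.0, 8.0, 4.0])  # halves every 10 min
        f = InputFunction(t, cp, cp)
        assert f.plasma_parent(70.0) == pytest.approx(2.0, rel=1e-6)
        assert f.plasma_parent(80.0) == pytest.approx(1.0, rel=1e-6)

    def test_pf_unity_and_plasma_equal_wb_gives_cp_equal_wb(self):
        t = np.array([2.5, 5.0, 10.0, 40.0, 80.0, 120.0])
        act = np.array([50.0, 40.0, 30.0, 12.0, 6.0, 3.0])
        blood = BloodSampleSet(t, act, act, np.ones(t.size))
        f = build_input_function(blood, auto=None)
        tt = np.linspace(0, 120, 200)
        assert np.allclose(f.plasma_parent(tt), f.whole_blood(tt), rtol=1e-9)

    def test_parent_never_exceeds_total_plasma_and_stays_nonnegative(self):
        blood, _, _ = generate_input_function(seed=3)
        f = build_input_function(blood, auto=None)
        tt = np.linspace(0, 120, 500)
        cp = np.asarray(f.plasma_parent(tt))
        total = np.interp(tt, blood.time_min, blood.plasma)
        inside = tt <= blood.time_min[-1]
        assert np.all(cp >= 0)
        assert np.all(cp[inside] <= total[inside] + 1e-9)

    def test_integral_consistent_with_fine_grid_quadrature(self):
        blood, auto, _ = generate_input_function(seed=0, noise=0.0)
        built = build_input_function(blood, auto)
        # integrating the assembled C_p on a routine grid must agree with a
        # very fine quadrature oracle of the same curve
        coarse = np.arange(0.0, 120.0 + 1e-9, 0.5)
        fine = np.linspace(0.0, 120.0, 1_440_001)
        got = np.trapezoid(np.asarray(built.plasma_parent(coarse)), coarse)
        oracle = np.trapezoid(np.asarray(built.plasma_parent(fine)), fine)
        assert got == pytest.approx(oracle, rel=5e-3)

    def test_order_invariance_of_sample_construction(self):
        t = np.array([2.5, 5.0, 10.0, 40.0, 80.0, 120.0])
        act = np.array([50.0, 40.0, 30.0, 12.0, 6.0, 3.0])
        rng = np.random.default_rng(1)
        perm = rng.permutation(t.size)
        a = BloodSampleSet(t, act, act)
        b = BloodSampleSet.from_unordered(t[perm], act[perm], act[perm])
        assert np.array_equal(a.time_min, b.time_min)
        assert np.array_equal(a.whole_blood, b.whole_blood)

    def test_coverage_gap_rejected(self):
        blood = BloodSampleSet(np.array([2.0, 110.0]), np.ones(2), np.ones(2))
        with pytest.raises(ValueError, match="gap"):
            build_input_function(blood)
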