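import numpy as np
import pytest

from petdisplace import (
    DisplacementParams,
    FrameSchedule,
    InputFunction,
    OccupancyProfile,
    OneTCMParams,
    TimeActivityCurve,
    simulate_1tcm,
    simulate_displacement,
)
from petdisplace.kinetics import (
    DisplacementModel,
    OneTissueModel,
    _SimGrid,
    frame_weights,
)


def _const_input(value, t_end=400.0, wb=None):
    t = np.array([0.0, t_end / 2, t_end])
    cp = np.full(3, value)
    wb_arr = np.full(3, value if wb is None else wb)
    return InputFunction(t, cp, wb_arr)


class TestForwardModel:
    def test_washout_closed_form(self, true_input, schedule):
        """With no input and initial tissue content c, the displacement model
        decays as c * exp(-k2 t / (1 + (1-d) BP_ND))."""
        zero_if = _const_input(0.0, t_end=120.0)
        grid = _SimGrid(schedule, zero_if, dt=0.5 / 60)
        k1, vt, vnd, d = 0.2, 15.0, 4.0, 0.6
        a_rate = (k1 / vnd) / (1 + (1 - d) * (vt / vnd - 1))
        C = grid.propagate(k1, np.full(grid.mid.shape, a_rate), c0=7.0)
        expected = 7.0 * np.exp(-a_rate * grid.nodes)
        assert np.allclose(C, expected, rtol=1e-3)

    def test_1tcm_equilibrates_at_vt_times_cp(self):
        sched = FrameSchedule.from_durations_s([600.0] * 40)  # 400 min
        f = _const_input(2.0)
        tac = simulate_1tcm(OneTCMParams(0.3, 10.0, 0.0), f, sched)
        assert tac.activity[-1] == pytest.approx(10.0 * 2.0, rel=1e-3)

    def test_k1_zero_leaves_only_blood_signal(self, true_input, schedule):
        tac = simulate_1tcm(OneTCMParams(0.0, 1.0, 0.05), true_input, schedule)
        grid = _SimGrid(schedule, true_input, dt=0.1 / 60)
        blood_only = grid.frame_average(0.05 * grid.wb_nodes)
        assert np.allclose(tac.activity, blood_only, rtol=1e-9)

    def test_convolution_oracle_on_exponential_input(self):
        """ODE integration against the analytic convolution
        K1 * A (e^{-k2 t} - e^{-a t}) / (a - k2) for C_p = A e^{-a t}."""
        A, alpha = 30.0, 0.08
        k1, vt = 0.25, 12.0
        k2 = k1 / vt
        t_dense = np.linspace(0.0, 120.0, 14_401)
        f = InputFunction(t_dense, A * np.exp(-alpha * t_dense), np.zeros_like(t_dense))
        sched = FrameSchedule.ucbj_120min()
        tac = simulate_1tcm(OneTCMParams(k1, vt, 0.0), f, sched)
        grid = _SimGrid(sched, f, dt=0.1 / 60)
        analytic = k1 * A * (np.exp(-k2 * grid.nodes) - np.exp(-alpha * grid.nodes)) / (
            alpha - k2
        )
        expected = grid.frame_average(analytic)
        assert np.allclose(tac.activity, expected, rtol=1e-3)

    def test_displacement_reduces_to_1tcm_when_occupancy_zero(
        self, true_input, schedule
    ):
        rng = np.random.default_rng(7)
        for _ in range(3):
            k1 = rng.uniform(0.05, 0.3)
            vt = rng.uniform(5, 25)
            vb = rng.uniform(0, 0.1)
            vnd = rng.uniform(1, vt)  # arbitrary V_ND: with d == 0 it must not matter
            p = OneTCMParams(k1, vt, vb)
            dp = DisplacementParams(regions={"r": p}, v_nd=vnd, occupancy=None)
            a = simulate_displacement(dp, true_input, schedule)[0].activity
            b = simulate_1tcm(p, true_input, schedule).activity
            assert np.allclose(a, b, rtol=1e-10)

    def test_euler_agrees_with_reference_integrator(
        self, displacement_truth, true_input, schedule
    ):
        """Forward Euler at the 0.1-s default step vs the adaptive high-order
        oracle: below 0.5 % on every frame."""
        two = DisplacementParams(
            regions={k: displacement_truth.regions[k] for k in ["hippocampus", "thalamus"]},
            v_nd=4.0,
            occupancy=displacement_truth.occupancy,
        )
        eu = simulate_displacement(two, true_input, schedule, solver="euler", dt=0.1 / 60)
        ref = simulate_displacement(two, true_input, schedule, solver="reference")
        for a, b in zip(eu, ref):
            assert np.max(np.abs(a.activity - b.activity) / np.abs(b.activity)) < 5e-3

    def test_single_step_is_limit_of_shrinking_ramp(self, true_input, schedule):
        """Numerical ramp with t_e -> t_b+ converges to the single step at t_s = t_b."""
        p = OneTCMParams(0.15, 16.0, 0.05)
        step = DisplacementParams(
            regions={"r": p}, v_nd=4.0,
            occupancy=OccupancyProfile("single_step", 0.7, 59.9, t_s=60.0),
        )
        target = simulate_displacement(step, true_input, schedule)[0].activity
        diffs = []
        for width in (8.0, 2.0, 0.5, 0.125):
            ramp = DisplacementParams(
                regions={"r": p}, v_nd=4.0,
                occupancy=OccupancyProfile("numerical_ramp", 0.7, 60.0, t_e=60.0 + width),
            )
            sim = simulate_displacement(ramp, true_input, schedule)[0].activity
            diffs.append(np.max(np.abs(sim - target)))
        assert all(d2 < d1 for d1, d2 in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-3 * target.max()

    def test_input_function_must_cover_schedule(self, schedule):
        short = InputFunction(np.array([0.0, 30.0, 60.0]), np.ones(3), np.ones(3))
        with pytest.raises(ValueError, match="cover"):
            simulate_1tcm(OneTCMParams(0.1, 10.0), short, schedule)


class TestFrameWeights:
    def test_decay_weights_favor_long_early_frames(self, schedule):
        w = frame_weights(schedule, "decay")
        assert w.mean() == pytest.approx(1.0)
        # among equal-duration frames, earlier ones weigh more
        last_nine = w[-9:]
        assert np.all(np.diff(last_nine) < 0)

    def test_uniform(self, schedule):
        assert np.all(frame_weights(schedule, "uniform") == 1.0)


class TestOneTissueFit:
    def test_noiseless_recovery_within_half_percent(self, true_input, schedule):
        truth = OneTCMParams(0.3, 15.0, 0.05)
        tac = simulate_1tcm(truth, true_input, schedule, dt=0.5 / 60)
        res = OneTissueModel(tac, true_input).fit()
        assert res.params.k1 == pytest.approx(0.3, rel=5e-3)
        assert res.params.vt == pytest.approx(15.0, rel=5e-3)
        assert res.params.vb == pytest.approx(0.05, rel=5e-3)
        assert res.converged

    def test_t_max_uses_only_frames_ending_before_cutoff(self, true_input, schedule):
        tac = simulate_1tcm(OneTCMParams(0.2, 10.0, 0.05), true_input, schedule)
        model = OneTissueModel(tac, true_input, t_max=60.0)
        assert model.tac.schedule.n_frames == int(np.sum(schedule.end <= 60.0))

    def test_blood_only_data_drives_k1_to_lower_bound(self, true_input, schedule):
        grid = _SimGrid(schedule, true_input, dt=0.5 / 60)
        blood_only = grid.frame_average(0.06 * grid.wb_nodes)
        tac = TimeActivityCurve("r", schedule, blood_only)
        res = OneTissueModel(tac, true_input).fit()
        assert res.params.k1 <= 1.1e-4  # pinned at the lower bound
        assert res.params.vb == pytest.approx(0.06, abs=5e-3)

    def test_refit_from_solution_does_not_improve(self, true_input, schedule):
        rng = np.random.default_rng(11)
        truth = OneTCMParams(0.22, 13.0, 0.04)
        tac0 = simulate_1tcm(truth, true_input, schedule, dt=0.5 / 60)
        noisy = TimeActivityCurve(
            "r", schedule, tac0.activity * (1 + 0.03 * rng.standard_normal(36))
        )
        m = OneTissueModel(noisy, true_input)
        first = m.fit()
        second = m.fit(x0=[first.params.k1, first.params.vt, first.params.vb])
        assert second.ssr <= first.ssr * (1 + 1e-8)

    def test_too_few_frames_rejected(self, true_input, schedule):
        tac = simulate_1tcm(OneTCMParams(0.2, 10.0), true_input, schedule)
        with pytest.raises(ValueError):
            OneTissueModel(tac, true_input, t_max=0.5)


class TestDisplacementFit:
    def test_noiseless_joint_recovery_within_one_percent(
        self, noiseless_fit, displacement_truth
    ):
        fit = noiseless_fit
        assert fit.converged
        assert fit.occupancy == pytest.approx(0.75, rel=0.01)
        assert fit.v_nd == pytest.approx(4.0, rel=0.01)
        assert fit.timing == pytest.approx(75.0, rel=0.01)
        for label, truth in displacement_truth.regions.items():
            est = fit.params.regions[label]
            assert est.k1 == pytest.approx(truth.k1, rel=0.01)
            assert est.vt == pytest.approx(truth.vt, rel=0.01)
            assert est.vb == pytest.approx(truth.vb, abs=0.002)

    def test_single_step_fit_recovers_step_truth(self, true_input, schedule):
        profile = OccupancyProfile("single_step", 0.7, 60.0, t_s=68.0)
        regions = {
            "a": OneTCMParams(0.12, 14.0, 0.05),
            "b": OneTCMParams(0.16, 19.0, 0.04),
            "c": OneTCMParams(0.10, 11.0, 0.06),
        }
        truth = DisplacementParams(regions=regions, v_nd=4.0, occupancy=profile)
        tacs = simulate_displacement(truth, true_input, schedule, dt=0.5 / 60)
        fit = DisplacementModel(
            tacs, true_input, t_b=60.0, solution="single_step", seed=1
        ).fit()
        assert fit.occupancy == pytest.approx(0.7, rel=0.01)
        assert fit.timing == pytest.approx(68.0, rel=0.01)
        assert fit.v_nd == pytest.approx(4.0, rel=0.02)

    def test_fitted_timing_strictly_after_drug_administration(self, noiseless_fit):
        assert noiseless_fit.timing > noiseless_fit.t_b

    def test_occupancy_within_open_unit_interval_and_vnd_below_regional_vt(
        self, noiseless_fit
    ):
        assert 0.0 < noiseless_fit.occupancy < 1.0
        assert noiseless_fit.v_nd <= min(
            p.vt for p in noiseless_fit.params.regions.values()
        )

    def test_mismatched_schedules_rejected(self, noiseless_tacs, true_input):
        other = TimeActivityCurve(
            "x",
            FrameSchedule.from_durations_s([60.0] * 120),
            np.ones(120),
        )
        with pytest.raises(ValueError, match="schedule"):
            DisplacementModel([noiseless_tacs[0], other], true_input, t_b=60.0)

    def test_t_b_outside_scan_rejected(self, noiseless_tacs, true_input):
        with pytest.raises(ValueError, match="t_b"):
            DisplacementModel(noiseless_tacs, true_input, t_b=130.0)
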