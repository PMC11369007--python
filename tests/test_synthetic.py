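import numpy as np
import pytest

from petdisplace import (
    FrameSchedule,
    LevPKParams,
    build_input_function,
    generate_input_function,
    generate_lev_pk,
    generate_study,
    generate_subject,
    lev_concentration,
    make_subject_truth,
    simulate_displacement,
)
from petdisplace.exposure import compute_auc
from petdisplace.synthetic import _average_exposure, _tac_noise_sd


class TestInputFunctionGenerator:
    def test_zero_noise_samples_equal_true_curve(self):
        from petdisplace.synthetic import InputFunctionParams

        params = InputFunctionParams()
        blood, auto, truth = generate_input_function(seed=1, params=params, noise=0.0)
        assert np.allclose(blood.whole_blood, params.whole_blood(blood.time_min))
        assert np.allclose(blood.plasma, params.plasma_total(blood.time_min))

    def test_same_seed_reproduces_identical_tables(self):
        b1, a1, _ = generate_input_function(seed=42)
        b2, a2, _ = generate_input_function(seed=42)
        assert np.array_equal(b1.whole_blood, b2.whole_blood)
        assert np.array_equal(b1.plasma, b2.plasma)
        assert np.array_equal(a1.counts, a2.counts)

    def test_round_trip_through_blood_pipeline_within_2_percent(self):
        """Rebuilding C_p from noiseless tables reproduces the true integral
        up to the piecewise-linear interpolation bias of the sparse late
        manual samples (chords overestimate a convex decaying curve)."""
        from petdisplace.synthetic import InputFunctionParams

        params = InputFunctionParams()
        blood, auto, truth = generate_input_function(seed=0, params=params, noise=0.0)
        built = build_input_function(blood, auto)
        tt = np.linspace(0.0, 120.0, 20_001)
        int_true = np.trapezoid(np.asarray(truth.plasma_parent(tt)), tt)
        int_built = np.trapezoid(np.asarray(built.plasma_parent(tt)), tt)
        assert int_built == pytest.approx(int_true, rel=0.02)


class TestLevPK:
    def test_zero_dose_gives_zero_concentration(self):
        s = generate_lev_pk(0.0, 78.0, "displacement", seed=0)
        assert np.all(s.concentration == 0.0)

    def test_concentration_continuous_at_end_of_infusion(self):
        p = LevPKParams()
        eps = 1e-6
        lo = lev_concentration(p.t_infusion - eps, 20.0, p)
        hi = lev_concentration(p.t_infusion + eps, 20.0, p)
        assert hi == pytest.approx(lo, rel=1e-4)

    def test_concentration_zero_before_infusion_starts(self):
        c = lev_concentration(np.array([-5.0, 0.0]), 20.0)
        assert np.all(c == 0.0)

    def test_dose_30_average_auc_in_reported_band(self):
        """At 30 mg/kg the displacement-scan average AUC should land in the
        50-100 ug/mL range seen at that dose in humans."""
        x = _average_exposure(30.0, 63.0, 63.0, 120.0, LevPKParams())
        assert 50.0 <= x <= 100.0

    def test_sampled_series_auc_tracks_true_exposure(self):
        s = generate_lev_pk(15.0, 78.0, "displacement", seed=5, t_dose=63.0, noise=0.0)
        sampled = compute_auc(s, 63.0, 120.0).average_auc
        true = _average_exposure(15.0, 63.0, 63.0, 120.0, LevPKParams())
        assert sampled == pytest.approx(true, rel=0.1)

    def test_block_scan_sampled_on_scan_clock(self):
        s = generate_lev_pk(15.0, 78.0, "block", seed=5)
        assert s.time_min[0] == pytest.approx(2.5)
        assert s.time_min[-1] == pytest.approx(120.0)
        assert np.all(s.concentration > 0)


class TestNoiseModel:
    def test_doubling_frame_duration_halves_variance(self):
        sched_short = FrameSchedule(np.array([0.0, 12.5]), np.array([10.0, 17.5]))
        sched_long = FrameSchedule(np.array([0.0, 10.0]), np.array([10.0, 20.0]))
        vals = np.array([50.0, 40.0])
        # same reference frame (0) and same midpoint (15 min) for the test frame
        sd_short = _tac_noise_sd(sched_short, vals, 0.05, reference_frame=0)
        sd_long = _tac_noise_sd(sched_long, vals, 0.05, reference_frame=0)
        assert (sd_short[1] / sd_long[1]) ** 2 == pytest.approx(2.0, rel=1e-9)

    def test_zero_noise_tacs_equal_forward_model(self):
        truth = make_subject_truth("S1", dose_mg_kg=20.0, seed=3)
        subj = generate_subject(truth, noise_level=0.0, seed=4)
        sim = simulate_displacement(
            truth.displacement_params(), subj.displacement_input_true, subj.schedule
        )
        for a, b in zip(subj.displacement_tacs, sim):
            assert np.array_equal(a.activity, b.activity)


class TestSubjectAndStudy:
    def test_block_truth_folds_constant_occupancy_into_vt(self):
        truth = make_subject_truth("S1", dose_mg_kg=20.0, seed=3)
        block = truth.block_params()
        for lab, p in truth.regions.items():
            expected = truth.v_nd + (1 - truth.block_occupancy) * (p.vt - truth.v_nd)
            assert block.regions[lab].vt == pytest.approx(expected)
        assert block.occupancy is None

    def test_same_day_subject_has_identical_baseline_vt_across_scans(self):
        truth = make_subject_truth("S1", 20.0, seed=3, same_day=True)
        assert truth.block_vt_factor is None

    def test_different_day_subject_gets_vt_perturbation(self):
        truth = make_subject_truth("S1", 20.0, seed=3, same_day=False,
                                   between_day_vt_sd=0.05)
        factors = np.array(list(truth.block_vt_factor.values()))
        assert factors.size == 7
        assert not np.allclose(factors, 1.0)

    def test_occupancy_truth_follows_emax_curve(self):
        truth = make_subject_truth("S1", 20.0, seed=3, true_emax=100.0, true_ic50=12.0)
        x = _average_exposure(20.0, 63.0, 63.0, 120.0, LevPKParams())
        assert truth.d_max == pytest.approx(x / (12.0 + x), rel=1e-6)

    def test_study_determinism_and_schema(self):
        a = generate_study(n_subjects=3, seed=11, noise_level=0.02)
        b = generate_study(n_subjects=3, seed=11, noise_level=0.02)
        assert len(a.subjects) == 3
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.truth.subject == sb.truth.subject
            for ta, tb in zip(sa.displacement_tacs, sb.displacement_tacs):
                assert np.array_equal(ta.activity, tb.activity)
            assert np.array_equal(
                sa.drug_block.concentration, sb.drug_block.concentration
            )
        m = a.manifest()
        assert list(m["subject"]) == ["S01", "S02", "S03"]
        assert np.all(m["true_d_max"].between(0, 1))

    def test_mixed_design_has_five_same_day_subjects(self):
        study = generate_study(n_subjects=11, seed=1, noise_level=0.0)
        flags = [s.truth.same_day for s in study.subjects]
        assert sum(flags) == 5
        doses = [s.truth.dose_mg_kg for s in study.subjects]
        assert min(doses) == 5.0 and max(doses) == 30.0
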