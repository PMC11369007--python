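"""Synthetic displacement studies with known ground truth.

Generates everything the pipeline consumes -- arterial blood tables, a
continuous autosampler series, seven regional TACs on the standard
120-min frame schedule, and plasma drug-concentration series for both a
displacement scan (drug infused ~60 min into the scan) and a block scan
(drug given ~2 h before injection) -- so that every stage is testable
without any acquired data.

Models emulated
---------------
* Tracer input: linear upslope over a 30-s bolus followed by a
  tri-exponential decay of total plasma activity; whole blood via a
  smooth plasma-to-whole-blood ratio; parent fraction from the sigmoid
  model of :mod:`petdisplace.blood`.
* Drug pharmacokinetics: two-compartment disposition with a 4-min
  zero-order infusion.  Defaults (central volume 0.25 L/kg, steady-state
  volume 0.6 L/kg, terminal half-life ~7 h, distribution rate chosen so
  the displacement-scan average AUC is ~2.2 ug/mL per mg/kg of dose)
  give exposures on the scale observed in human studies at 5-30 mg/kg.
* Occupancy ground truth: maximal displacement-scan occupancy and the
  constant block-scan occupancy both follow a configured true Emax
  curve evaluated at the scan's average drug exposure.
* TAC noise: Gaussian, variance proportional to signal over (frame
  duration x physical decay factor), parameterized as a fractional
  level at a reference late frame.

All randomness flows from a single integer seed; regenerating with the
same seed yields identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blood import (
    AutosamplerSeries,
    BloodSampleSet,
    C11_HALF_LIFE_MIN,
    InputFunction,
    ParentFractionModel,
    decay_uncorrect,
)
from .exposure import PlasmaDrugSeries
from .frames import FrameSchedule, TimeActivityCurve
from .kinetics import DEFAULT_DT_MIN, DisplacementParams, OneTCMParams, simulate_displacement
from .occupancy import OccupancyProfile

__all__ = [
    "REGION_DEFAULTS",
    "InputFunctionParams",
    "LevPKParams",
    "SubjectTruth",
    "SubjectData",
    "StudyDataset",
    "lev_concentration",
    "generate_input_function",
    "generate_lev_pk",
    "generate_subject",
    "generate_study",
]

#: Default regional 1TCM parameters (K1 mL/cm3/min, baseline V_T mL/cm3, v_B).
REGION_DEFAULTS: dict[str, OneTCMParams] = {
    "hippocampus": OneTCMParams(0.10, 12.0, 0.04),
    "frontal cortex": OneTCMParams(0.13, 16.0, 0.05),
    "temporal cortex": OneTCMParams(0.12, 15.0, 0.05),
    "striatum": OneTCMParams(0.14, 18.0, 0.05),
    "posterior cingulate": OneTCMParams(0.15, 20.0, 0.06),
    "thalamus": OneTCMParams(0.16, 14.0, 0.06),
    "insula": OneTCMParams(0.13, 17.0, 0.05),
}

#: Manual arterial sampling times, minutes (first = displacement scan).
MANUAL_TIMES_DISPLACEMENT = np.array(
    [2.5, 5, 10, 25, 40, 55, 57.5, 60, 65, 70, 90, 105, 120], float
)
MANUAL_TIMES_BLOCK = np.array([2.5, 5, 10, 25, 40, 60, 80, 100, 120], float)

#: Drug-sampling times: minutes after infusion start (displacement scan)
#: and minutes after tracer injection (block scan).
LEV_DRAWS_POST_INFUSION = np.array([2.5, 5, 10, 15, 30, 45, 60], float)
LEV_DRAWS_BLOCK_SCAN = np.array([2.5, 5, 10, 25, 40, 60, 80, 100, 120], float)


# ---------------------------------------------------------------------------
# tracer input function


@dataclass(frozen=True)
class InputFunctionParams:
    """Tri-exponential bolus model of total plasma activity.

    Total plasma activity rises linearly over ``t_rise`` minutes to
    ``peak`` kBq/mL and then decays as a weighted sum of three
    exponentials; whole blood is plasma times a smooth ratio
    ``wb_ratio_inf + wb_ratio_amp * exp(-t / wb_ratio_tau)``.
    """

    peak: float = 80.0
    t_rise: float = 0.5
    fractions: tuple[float, float, float] = (0.25, 0.25, 0.5)
    rates: tuple[float, float, float] = (4.0, 0.25, 0.012)  # 1/min
    wb_ratio_inf: float = 0.75
    wb_ratio_amp: float = 0.25
    wb_ratio_tau: float = 40.0
    parent_fraction: ParentFractionModel = field(default_factory=ParentFractionModel)
    sample_noise: float = 0.02  # fractional SD on manual samples
    autosampler_cal: float = 2.5  # kBq/mL per count unit (true factor)
    autosampler_background: float = 30.0  # counts
    autosampler_noise: float = 1.5  # counts SD at background level
    autosampler_minutes: float = 10.0

    def plasma_total(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        tau = np.clip(t / self.t_rise, 0.0, 1.0)
        f = np.array(self.fractions) / sum(self.fractions)
        decay = sum(
            fi * np.exp(-ri * np.clip(t - self.t_rise, 0.0, None))
            for fi, ri in zip(f, self.rates)
        )
        return np.where(t <= self.t_rise, self.peak * tau, self.peak * decay)

    def whole_blood(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        ratio = self.wb_ratio_inf + self.wb_ratio_amp * np.exp(-t / self.wb_ratio_tau)
        return self.plasma_total(t) * ratio

    def plasma_parent(self, t) -> np.ndarray:
        return self.plasma_total(t) * np.asarray(self.parent_fraction(t), float)

    def true_input_function(self, t_end: float, dt: float = 0.05) -> InputFunction:
        """Noise-free input function on a dense grid (the ground truth)."""
        t = np.arange(0.0, t_end + dt / 2, dt)
        return InputFunction(t, self.plasma_parent(t), self.whole_blood(t))


def generate_input_function(
    seed: int,
    schedule: FrameSchedule | None = None,
    scan: str = "displacement",
    params: InputFunctionParams | None = None,
    noise: float | None = None,
) -> tuple[BloodSampleSet, AutosamplerSeries, InputFunction]:
    """Generate blood tables plus the underlying true input function.

    Returns ``(manual_samples, autosampler, truth)``.  ``noise`` overrides
    the fractional manual-sample noise (``0`` gives exact samples).
    """
    if schedule is None:
        schedule = FrameSchedule.ucbj_120min()
    if params is None:
        params = InputFunctionParams()
    if noise is not None:
        params = replace(params, sample_noise=noise)
    rng = np.random.default_rng(seed)
    t_end = float(schedule.end[-1])

    times = MANUAL_TIMES_DISPLACEMENT if scan == "displacement" else MANUAL_TIMES_BLOCK
    times = times[times <= t_end + 1e-9]
    wb_true = params.whole_blood(times)
    pl_true = params.plasma_total(times)
    pf_true = np.asarray(params.parent_fraction(times), float)
    s = params.sample_noise
    wb = np.clip(wb_true * (1 + s * rng.standard_normal(times.size)), 0, None)
    pl = np.clip(pl_true * (1 + s * rng.standard_normal(times.size)), 0, None)
    pf = np.clip(pf_true * (1 + 0.5 * s * rng.standard_normal(times.size)), 0, 1)
    manual = BloodSampleSet(times, wb, pl, pf)

    t_s = np.arange(0.0, params.autosampler_minutes * 60.0 + 0.5, 1.0)
    wb_auto_true = params.whole_blood(t_s / 60.0)
    counts_true = (
        decay_uncorrect(wb_auto_true, t_s / 60.0) / params.autosampler_cal
        + params.autosampler_background
    )
    noise_sd = params.autosampler_noise * np.sqrt(
        np.maximum(counts_true / params.autosampler_background, 1.0)
    )
    counts = counts_true + (s > 0) * noise_sd * rng.standard_normal(t_s.size)
    auto = AutosamplerSeries(t_s, np.clip(counts, 0, None), params.autosampler_background)

    return manual, auto, params.true_input_function(t_end)


# ---------------------------------------------------------------------------
# drug pharmacokinetics


@dataclass(frozen=True)
class LevPKParams:
    """Two-compartment drug disposition, per-kg parameterization.

    ``v1``/``v2`` central and peripheral volumes (L/kg), ``cl`` clearance
    (L/kg/min; default gives a ~7-h terminal half-life on a 0.6 L/kg
    steady-state volume), ``k12`` central-to-peripheral rate (1/min;
    calibrated so a displacement-scan average AUC of ~2.2 ug/mL per
    mg/kg of dose results), ``t_infusion`` the zero-order infusion
    duration (minutes).
    """

    v1: float = 0.25
    v2: float = 0.35
    cl: float = 0.6 * np.log(2.0) / 420.0
    k12: float = 0.03
    t_infusion: float = 4.0

    @property
    def k10(self) -> float:
        return self.cl / self.v1

    @property
    def k21(self) -> float:
        return self.k12 * self.v1 / self.v2


def lev_concentration(
    t_post_dose, dose_mg_kg: float, params: LevPKParams | None = None
) -> np.ndarray:
    """Plasma drug concentration (ug/mL) at times after infusion start (min).

    Closed-form solution of the two-compartment model under a zero-order
    infusion of ``dose_mg_kg`` over ``params.t_infusion`` minutes; zero
    before the infusion starts and continuous at its end.
    """
    if params is None:
        params = LevPKParams()
    if dose_mg_kg < 0:
        raise ValueError("dose must be nonnegative")
    t = np.asarray(t_post_dose, float)
    if dose_mg_kg == 0:
        return np.zeros_like(t)
    A = np.array(
        [[-(params.k10 + params.k12), params.k21], [params.k12, -params.k21]]
    )
    lam, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)
    rate = dose_mg_kg / params.t_infusion  # mg/kg/min into central compartment
    w = Vinv @ np.array([rate, 0.0])

    tt = np.clip(t, 0.0, None)
    t_inf = np.minimum(tt, params.t_infusion)  # infusion-phase time
    t_post = np.clip(tt - params.t_infusion, 0.0, None)
    # x(t) = V diag(e^{lam t_post}) (e^{lam t_inf} - 1)/lam w
    core = np.exp(np.outer(lam, t_post)) * (
        (np.exp(np.outer(lam, t_inf)) - 1.0) / lam[:, None]
    )
    x0 = (V @ (core * w[:, None]))[0]
    conc = np.where(t > 0, x0 / params.v1, 0.0)
    return np.clip(conc.real, 0.0, None)


def generate_lev_pk(
    dose_mg_kg: float,
    weight_kg: float,
    scan: str,
    seed: int,
    t_dose: float | None = None,
    params: LevPKParams | None = None,
    noise: float = 0.03,
    subject: str = "",
) -> PlasmaDrugSeries:
    """Sampled plasma drug concentrations for one scan.

    For a displacement scan the drug is infused at ``t_dose`` minutes
    after scan start (default 63) and samples are drawn at the standard
    post-infusion times; for a block scan the drug was given ``-t_dose``
    minutes before scan start (default t_dose = -120) and samples are
    drawn on the scan clock.  Disposition is weight-independent in the
    per-kg parameterization; ``weight_kg`` is carried for dose records.
    """
    if scan not in ("displacement", "block"):
        raise ValueError("scan must be 'displacement' or 'block'")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    params = params or LevPKParams()
    rng = np.random.default_rng(seed)
    if scan == "displacement":
        t_dose = 63.0 if t_dose is None else t_dose
        draw_times = np.concatenate([[t_dose], t_dose + LEV_DRAWS_POST_INFUSION])
    else:
        t_dose = -120.0 if t_dose is None else t_dose
        draw_times = LEV_DRAWS_BLOCK_SCAN.copy()
    conc_true = lev_concentration(draw_times - t_dose, dose_mg_kg, params)
    conc = np.clip(conc_true * (1 + noise * rng.standard_normal(draw_times.size)), 0, None)
    conc[conc_true == 0] = 0.0
    return PlasmaDrugSeries(draw_times, conc, subject=subject, scan=scan)


def _average_exposure(
    dose_mg_kg: float, t_dose: float, t_start: float, t_end: float,
    params: LevPKParams,
) -> float:
    """True average AUC (ug/mL) of the drug curve over a scan window."""
    t = np.linspace(t_start, t_end, 961)
    c = lev_concentration(t - t_dose, dose_mg_kg, params)
    return float(np.trapezoid(c, t) / (t_end - t_start))


# ---------------------------------------------------------------------------
# subjects and studies


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth description of one synthetic subject."""

    subject: str
    regions: dict[str, OneTCMParams]
    v_nd: float
    dose_mg_kg: float
    weight_kg: float
    t_b: float  # displacement-scan drug time, min after scan start
    te_offset: float  # true t_e - t_b, min
    d_max: float  # true maximal occupancy, displacement scan
    block_occupancy: float  # true constant occupancy, block scan
    block_t_dose: float = -120.0
    same_day: bool = True
    block_vt_factor: dict[str, float] | None = None  # between-day V_T perturbation

    def __post_init__(self) -> None:
        if self.dose_mg_kg <= 0:
            raise ValueError("dose must be positive")
        if not (0.0 < self.d_max < 1.0) or not (0.0 < self.block_occupancy < 1.0):
            raise ValueError("true occupancies must lie in (0, 1)")

    @property
    def occupancy_profile(self) -> OccupancyProfile:
        return OccupancyProfile(
            "numerical_ramp", self.d_max, self.t_b, t_e=self.t_b + self.te_offset
        )

    def displacement_params(self) -> DisplacementParams:
        return DisplacementParams(
            regions=self.regions, v_nd=self.v_nd, occupancy=self.occupancy_profile
        )

    def block_params(self) -> DisplacementParams:
        """Block scan: constant occupancy folded into reduced regional V_T."""
        occ = self.block_occupancy
        regions = {}
        for lab, p in self.regions.items():
            vt_base = p.vt
            if self.block_vt_factor is not None:
                vt_base = vt_base * self.block_vt_factor[lab]
            vt_block = self.v_nd + (1.0 - occ) * (vt_base - self.v_nd)
            regions[lab] = OneTCMParams(p.k1, vt_block, p.vb)
        return DisplacementParams(regions=regions, v_nd=self.v_nd, occupancy=None)


@dataclass(frozen=True)
class SubjectData:
    """All measured materials of one synthetic subject (both scans)."""

    truth: SubjectTruth
    schedule: FrameSchedule
    displacement_tacs: list[TimeActivityCurve]
    displacement_blood: BloodSampleSet
    displacement_auto: AutosamplerSeries
    displacement_input_true: InputFunction
    block_tacs: list[TimeActivityCurve]
    block_blood: BloodSampleSet
    block_auto: AutosamplerSeries
    block_input_true: InputFunction
    drug_displacement: PlasmaDrugSeries
    drug_block: PlasmaDrugSeries


@dataclass(frozen=True)
class StudyDataset:
    """A complete synthetic multi-subject study with its generation seed."""

    subjects: list[SubjectData]
    seed: int
    true_emax: float
    true_ic50: float
    noise_level: float

    def manifest(self) -> pd.DataFrame:
        """Per-subject ground-truth table for test harnesses."""
        rows = []
        for s in self.subjects:
            t = s.truth
            rows.append(
                {
                    "subject": t.subject,
                    "same_day": t.same_day,
                    "dose_mg_kg": t.dose_mg_kg,
                    "weight_kg": t.weight_kg,
                    "t_b": t.t_b,
                    "true_d_max": t.d_max,
                    "true_block_occupancy": t.block_occupancy,
                    "true_v_nd": t.v_nd,
                    "true_t_e": t.t_b + t.te_offset,
                }
            )
        return pd.DataFrame(rows)


def _tac_noise_sd(
    schedule: FrameSchedule, tac_values: np.ndarray, noise_level: float,
    reference_frame: int,
) -> np.ndarray:
    """Frame-wise noise SD: variance ~ signal / (duration x decay factor)."""
    lam = np.log(2.0) / C11_HALF_LIFE_MIN
    u = np.sqrt(
        np.maximum(tac_values, 1e-6)
        / (schedule.duration * np.exp(-lam * schedule.mid))
    )
    ref = max(tac_values[reference_frame], 1e-6)
    return noise_level * ref * u / u[reference_frame]


def generate_subject(
    truth: SubjectTruth,
    noise_level: float,
    seed: int,
    schedule: FrameSchedule | None = None,
    if_params: InputFunctionParams | None = None,
    pk_params: LevPKParams | None = None,
    dt: float = DEFAULT_DT_MIN,
) -> SubjectData:
    """Generate both scans of one subject from its ground truth.

    ``noise_level`` is the fractional TAC noise at the reference late
    frame (0 gives exact forward-model values); blood-sample noise scales
    with it.
    """
    if schedule is None:
        schedule = FrameSchedule.ucbj_120min()
    if if_params is None:
        if_params = InputFunctionParams()
    pk_params = pk_params or LevPKParams()
    rng = np.random.default_rng(seed)
    blood_noise = 0.0 if noise_level == 0 else if_params.sample_noise
    # reference frame: first 600-s frame (late enough that decay matters)
    ref_frame = int(np.argmax(schedule.duration >= 10.0 - 1e-9))

    def make_scan(scan: str, params: DisplacementParams):
        sub_seed = rng.integers(0, 2**31 - 1)
        blood, auto, if_true = generate_input_function(
            int(sub_seed), schedule, scan=scan, params=if_params, noise=blood_noise
        )
        tacs = simulate_displacement(params, if_true, schedule, solver="euler", dt=dt)
        noisy = []
        for tac in tacs:
            if noise_level > 0:
                sd = _tac_noise_sd(schedule, tac.activity, noise_level, ref_frame)
                vals = tac.activity + sd * rng.standard_normal(tac.activity.size)
            else:
                vals = tac.activity
            noisy.append(TimeActivityCurve(tac.region, schedule, vals))
        return blood, auto, if_true, noisy

    d_blood, d_auto, d_if, d_tacs = make_scan(
        "displacement", truth.displacement_params()
    )
    b_blood, b_auto, b_if, b_tacs = make_scan("block", truth.block_params())

    drug_noise = 0.0 if noise_level == 0 else 0.03
    drug_disp = generate_lev_pk(
        truth.dose_mg_kg, truth.weight_kg, "displacement",
        int(rng.integers(0, 2**31 - 1)), t_dose=truth.t_b,
        params=pk_params, noise=drug_noise, subject=truth.subject,
    )
    drug_block = generate_lev_pk(
        truth.dose_mg_kg, truth.weight_kg, "block",
        int(rng.integers(0, 2**31 - 1)), t_dose=truth.block_t_dose,
        params=pk_params, noise=drug_noise, subject=truth.subject,
    )
    return SubjectData(
        truth=truth,
        schedule=schedule,
        displacement_tacs=d_tacs,
        displacement_blood=d_blood,
        displacement_auto=d_auto,
        displacement_input_true=d_if,
        block_tacs=b_tacs,
        block_blood=b_blood,
        block_auto=b_auto,
        block_input_true=b_if,
        drug_displacement=drug_disp,
        drug_block=drug_block,
    )


def make_subject_truth(
    subject: str,
    dose_mg_kg: float,
    seed: int,
    *,
    weight_kg: float = 78.0,
    t_b: float = 63.0,
    te_offset: float = 15.0,
    v_nd: float = 4.0,
    true_emax: float = 100.0,
    true_ic50: float = 12.0,
    same_day: bool = True,
    between_day_vt_sd: float = 0.0,
    regions: dict[str, OneTCMParams] | None = None,
    pk_params: LevPKParams | None = None,
    scan_end: float = 120.0,
) -> SubjectTruth:
    """Build one subject's ground truth, with mild regional variation.

    The true maximal occupancy of the displacement scan and the constant
    block-scan occupancy are read off the true Emax curve at each scan's
    average drug exposure (the PK-implied value).
    """
    rng = np.random.default_rng(seed)
    pk_params = pk_params or LevPKParams()
    base = regions or REGION_DEFAULTS
    jittered = {
        lab: OneTCMParams(
            p.k1 * rng.lognormal(0.0, 0.08),
            p.vt * rng.lognormal(0.0, 0.08),
            float(np.clip(p.vb * rng.lognormal(0.0, 0.1), 0.0, 0.2)),
        )
        for lab, p in base.items()
    }
    x_disp = _average_exposure(dose_mg_kg, t_b, t_b, scan_end, pk_params)
    x_block = _average_exposure(dose_mg_kg, -120.0, 0.0, scan_end, pk_params)
    occ = lambda x: np.clip(true_emax * x / (true_ic50 + x) / 100.0, 1e-3, 1 - 1e-3)
    vt_factor = None
    if between_day_vt_sd > 0:
        vt_factor = {
            lab: float(rng.lognormal(0.0, between_day_vt_sd)) for lab in jittered
        }
    return SubjectTruth(
        subject=subject,
        regions=jittered,
        v_nd=v_nd,
        dose_mg_kg=dose_mg_kg,
        weight_kg=weight_kg,
        t_b=t_b,
        te_offset=te_offset,
        d_max=float(occ(x_disp)),
        block_occupancy=float(occ(x_block)),
        same_day=same_day,
        block_vt_factor=vt_factor,
    )


def generate_study(
    n_subjects: int = 11,
    dose_range: tuple[float, float] = (5.0, 30.0),
    design: str = "mixed",
    seed: int = 0,
    *,
    true_emax: float = 100.0,
    true_ic50: float = 12.0,
    noise_level: float = 0.02,
    between_day_vt_sd: float = 0.05,
    dt: float = DEFAULT_DT_MIN,
) -> StudyDataset:
    """Generate a complete paired displacement + block study.

    ``design`` is ``"same_day"`` (no between-day V_T change),
    ``"different_day"`` (every subject gets a multiplicative V_T
    test-retest perturbation of SD ``between_day_vt_sd``), or ``"mixed"``
    (five same-day subjects, the rest different-day, as in the human
    validation cohort).  Doses are spread linearly over ``dose_range``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if design not in ("mixed", "same_day", "different_day"):
        raise ValueError("design must be 'mixed', 'same_day' or 'different_day'")
    rng = np.random.default_rng(seed)
    doses = np.linspace(dose_range[0], dose_range[1], n_subjects)
    if design == "mixed":
        n_same = min(5, n_subjects)
        flags = np.array([True] * n_same + [False] * (n_subjects - n_same))
        rng.shuffle(flags)
    else:
        flags = np.full(n_subjects, design == "same_day")
    subjects = []
    for i in range(n_subjects):
        t_b = float(np.clip(rng.normal(63.0, 3.7), 56.0, 67.0))
        weight = float(np.clip(rng.normal(78.0, 18.0), 50.0, 110.0))
        truth = make_subject_truth(
            subject=f"S{i + 1:02d}",
            dose_mg_kg=float(doses[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
            weight_kg=weight,
            t_b=t_b,
            te_offset=float(np.clip(rng.normal(15.0, 5.0), 5.0, 40.0)),
            true_emax=true_emax,
            true_ic50=true_ic50,
            same_day=bool(flags[i]),
            between_day_vt_sd=0.0 if flags[i] else between_day_vt_sd,
        )
        subjects.append(
            generate_subject(
                truth, noise_level, int(rng.integers(0, 2**31 - 1)), dt=dt
            )
        )
    return StudyDataset(
        subjects=subjects,
        seed=seed,
        true_emax=true_emax,
        true_ic50=true_ic50,
        noise_level=noise_level,
    )
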