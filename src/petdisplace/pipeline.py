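"""End-to-end study analysis: from raw per-subject tables to result tables.

For every subject the pipeline (i) assembles the metabolite-corrected
input functions from the blood tables, (ii) fits the displacement model
to the displacement scan with both the numerical and the single-step
solution, (iii) estimates baseline V_T from the pre-drug segment and
block-scan V_T from the full second scan and applies the Lassen plot,
and (iv) summarizes drug exposure (AUC) for both scans.  Pooled across
subjects it then fits the Emax exposure-occupancy model per method
(Emax free and fixed at 100 %), runs the extra-sum-of-squares F tests,
the Bland-Altman comparisons (overall and same-day/different-day
subgroups) and the Kruskal-Wallis tests across methods.

Per-subject failures are isolated and logged, never fatal to the batch.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import BlandAltmanResult, bland_altman, kruskal_wallis
from .blood import AutosamplerSeries, BloodSampleSet, build_input_function
from .exposure import (
    EmaxResults,
    ExposureSummary,
    FTestResult,
    PlasmaDrugSeries,
    compute_auc,
    extra_ss_f_test,
    fit_emax,
)
from .frames import TimeActivityCurve
from .io import (
    occupancy_records_frame,
    read_autosampler_table,
    read_blood_table,
    read_drug_table,
    read_tac_table,
    write_autosampler_table,
    write_blood_table,
    write_drug_table,
    write_json_report,
    write_occupancy_records,
    write_tac_table,
)
from .kinetics import DEFAULT_FIT_DT_MIN, DisplacementModel, OneTissueModel
from .lassen import LassenPlot, OccupancyRecord, baseline_vt, occupancy_from_displacement
from .synthetic import StudyDataset, SubjectData

__all__ = [
    "AnalysisOptions",
    "StudyConfig",
    "SubjectInputs",
    "ResultsBundle",
    "run_study_analysis",
    "write_study",
    "load_study",
]

DISPLACEMENT_METHODS = ("numerical", "single_step")
ALL_METHODS = ("numerical", "single_step", "lassen")


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable analysis settings (defaults reproduce the standard pipeline)."""

    weights: str = "decay"
    dt: float = DEFAULT_FIT_DT_MIN
    n_starts: int = 3
    seed: int = 0
    use_true_input: bool = False  # use generator truth input functions (tests)
    min_baseline_min: float = 30.0

    def __post_init__(self) -> None:
        if self.weights not in ("decay", "uniform"):
            raise ValueError("weights must be 'decay' or 'uniform'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class StudyConfig:
    """File-based study description: where the tables live, how to analyze."""

    root: str
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    output_dir: str | None = None

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = json.load(fh)
        opts = AnalysisOptions(**raw.get("options", {}))
        return cls(root=raw["root"], options=opts, output_dir=raw.get("output_dir"))

    def to_json(self, path) -> None:
        payload = {"root": self.root, "options": asdict(self.options)}
        if self.output_dir:
            payload["output_dir"] = self.output_dir
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass(frozen=True)
class SubjectInputs:
    """Everything the pipeline needs for one subject (both scans)."""

    subject: str
    t_b: float
    dose_mg_kg: float
    weight_kg: float
    same_day: bool
    displacement_tacs: list[TimeActivityCurve]
    displacement_blood: BloodSampleSet
    displacement_auto: AutosamplerSeries | None
    block_tacs: list[TimeActivityCurve]
    block_blood: BloodSampleSet
    block_auto: AutosamplerSeries | None
    drug_displacement: PlasmaDrugSeries
    drug_block: PlasmaDrugSeries
    displacement_input_true: object | None = None
    block_input_true: object | None = None

    @classmethod
    def from_subject_data(cls, s: SubjectData) -> "SubjectInputs":
        return cls(
            subject=s.truth.subject,
            t_b=s.truth.t_b,
            dose_mg_kg=s.truth.dose_mg_kg,
            weight_kg=s.truth.weight_kg,
            same_day=s.truth.same_day,
            displacement_tacs=s.displacement_tacs,
            displacement_blood=s.displacement_blood,
            displacement_auto=s.displacement_auto,
            block_tacs=s.block_tacs,
            block_blood=s.block_blood,
            block_auto=s.block_auto,
            drug_displacement=s.drug_displacement,
            drug_block=s.drug_block,
            displacement_input_true=s.displacement_input_true,
            block_input_true=s.block_input_true,
        )


@dataclass
class SubjectResults:
    """Per-subject intermediate results."""

    subject: str
    records: list[OccupancyRecord]
    baseline_vt: dict[str, float]
    block_vt: dict[str, float]
    exposures: dict[str, ExposureSummary]
    displacement_fits: dict


@dataclass
class ResultsBundle:
    """Pooled study results: records, Emax fits, F tests, agreement, log."""

    records: list[OccupancyRecord]
    subject_results: dict[str, SubjectResults]
    emax: dict[tuple[str, str, bool], EmaxResults]
    f_tests: dict[tuple[str, str], FTestResult]
    bland_altman: dict[tuple[str, str, str], BlandAltmanResult]
    kruskal: dict[str, tuple[float, float]]
    exposures: pd.DataFrame
    log: list[str]
    errors: dict[str, str]
    seed: int

    def records_frame(self) -> pd.DataFrame:
        return occupancy_records_frame(self.records)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_occupancy_records(directory / "occupancy_records.csv", self.records)
        self.exposures.to_csv(directory / "exposures.csv", index=False)
        report = {
            "seed": self.seed,
            "emax": {
                f"{m}|{kind}|{'fixed' if fx else 'free'}": {
                    "emax": r.emax, "ic50": r.ic50, "r_squared": r.r_squared,
                    "ssr": r.ssr, "df": r.df,
                }
                for (m, kind, fx), r in self.emax.items()
            },
            "f_tests": {
                f"{m}|{kind}": {"F": t.f_statistic, "p": t.p_value}
                for (m, kind), t in self.f_tests.items()
            },
            "bland_altman": {
                f"{a}|{b}|{sub}": {
                    "bias": r.bias, "sd": r.sd_differences, "cv_percent": r.cv_percent,
                }
                for (a, b, sub), r in self.bland_altman.items()
            },
            "kruskal_wallis": {k: {"H": v[0], "p": v[1]} for k, v in self.kruskal.items()},
            "errors": self.errors,
            "log": self.log,
        }
        write_json_report(directory / "study_report.json", report)


def _analyze_subject(inp: SubjectInputs, opts: AnalysisOptions, seed: int) -> SubjectResults:
    scan_end = float(inp.displacement_tacs[0].schedule.end[-1])
    if opts.use_true_input and inp.displacement_input_true is not None:
        disp_if = inp.displacement_input_true
        block_if = inp.block_input_true
    else:
        disp_if = build_input_function(inp.displacement_blood, inp.displacement_auto)
        block_if = build_input_function(inp.block_blood, inp.block_auto)

    fits = {}
    records = []
    for method in DISPLACEMENT_METHODS:
        fit = DisplacementModel(
            inp.displacement_tacs, disp_if, inp.t_b, solution=method,
            weights=opts.weights, dt=opts.dt, n_starts=opts.n_starts, seed=seed,
        ).fit()
        fits[method] = fit
        records.append(
            occupancy_from_displacement(fit, subject=inp.subject,
                                        dose_mg_kg=inp.dose_mg_kg)
        )

    base_vt = baseline_vt(
        inp.displacement_tacs, disp_if, inp.t_b,
        weights=opts.weights, min_segment_min=opts.min_baseline_min, dt=opts.dt,
    )
    block_vt = {
        tac.region: OneTissueModel(
            tac, block_if, weights=opts.weights, dt=opts.dt
        ).fit().params.vt
        for tac in inp.block_tacs
    }
    regions = [t.region for t in inp.displacement_tacs]
    lassen = LassenPlot(
        [base_vt[r] for r in regions], [block_vt[r] for r in regions], regions
    ).fit()
    records.append(
        OccupancyRecord(
            subject=inp.subject,
            method="lassen",
            occupancy_percent=float(np.clip(lassen.occupancy_percent, 0.0, 100.0)),
            v_nd=lassen.v_nd,
            dose_mg_kg=inp.dose_mg_kg,
            converged=lassen.reliable,
        )
    )

    exposures = {
        "displacement": compute_auc(inp.drug_displacement, inp.t_b, scan_end),
        "block": compute_auc(inp.drug_block, 0.0, scan_end),
    }
    return SubjectResults(
        subject=inp.subject,
        records=records,
        baseline_vt=base_vt,
        block_vt=block_vt,
        exposures=exposures,
        displacement_fits=fits,
    )


def run_study_analysis(study, options: AnalysisOptions | None = None) -> ResultsBundle:
    """Run the full analysis on a study.

    ``study`` is a :class:`~petdisplace.synthetic.StudyDataset`, a list of
    :class:`SubjectInputs`, or a :class:`StudyConfig` pointing at tables
    on disk.  Deterministic for a fixed dataset and options.
    """
    output_dir = None
    if isinstance(study, StudyConfig):
        options = options or study.options
        output_dir = study.output_dir
        inputs = load_study(study.root)
    elif isinstance(study, StudyDataset):
        inputs = [SubjectInputs.from_subject_data(s) for s in study.subjects]
    else:
        inputs = list(study)
    opts = options or AnalysisOptions()

    log, errors = [], {}
    subject_results: dict[str, SubjectResults] = {}
    for i, inp in enumerate(inputs):
        try:
            seed = (opts.seed + 7919 * i) % (2**31 - 1)
            subject_results[inp.subject] = _analyze_subject(inp, opts, seed)
            log.append(f"{inp.subject}: ok")
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            errors[inp.subject] = "".join(
                traceback.format_exception_only(type(exc), exc)
            ).strip()
            log.append(f"{inp.subject}: FAILED ({errors[inp.subject]})")

    records = [r for sr in subject_results.values() for r in sr.records]
    same_day = {
        inp.subject: inp.same_day for inp in inputs if inp.subject in subject_results
    }

    occ = {
        m: np.array(
            [
                next(r.occupancy_percent for r in sr.records if r.method == m)
                for sr in subject_results.values()
            ]
        )
        for m in ALL_METHODS
    }
    vnd = {
        m: np.array(
            [
                next(r.v_nd for r in sr.records if r.method == m)
                for sr in subject_results.values()
            ]
        )
        for m in ALL_METHODS
    }
    sd_flags = np.array([same_day[s] for s in subject_results])

    exposures = pd.DataFrame(
        [
            {
                "subject": s,
                "same_day": same_day[s],
                "total_auc_displacement": sr.exposures["displacement"].total_auc,
                "avg_auc_displacement": sr.exposures["displacement"].average_auc,
                "total_auc_block": sr.exposures["block"].total_auc,
                "avg_auc_block": sr.exposures["block"].average_auc,
            }
            for s, sr in subject_results.items()
        ]
    )

    emax, f_tests = {}, {}
    if len(subject_results) >= 3:
        for m in ALL_METHODS:
            scan = "block" if m == "lassen" else "displacement"
            for kind in ("average", "total"):
                col = f"{'avg' if kind == 'average' else 'total'}_auc_{scan}"
                x = exposures[col].to_numpy()
                y = occ[m]
                try:
                    free = fit_emax(x, y, fix_emax_100=False)
                    fixed = fit_emax(x, y, fix_emax_100=True)
                except (ValueError, RuntimeError) as exc:
                    log.append(f"emax {m}/{kind}: FAILED ({exc})")
                    continue
                emax[(m, kind, False)] = free
                emax[(m, kind, True)] = fixed
                f_tests[(m, kind)] = extra_ss_f_test(fixed, free)

    ba = {}
    if len(subject_results) >= 2:
        for m in DISPLACEMENT_METHODS:
            ba[(m, "lassen", "all")] = bland_altman(occ[m], occ["lassen"])
            for sub, mask in [("same_day", sd_flags), ("different_day", ~sd_flags)]:
                if mask.sum() >= 2:
                    ba[(m, "lassen", sub)] = bland_altman(
                        occ[m][mask], occ["lassen"][mask]
                    )
        ba[("numerical", "single_step", "all")] = bland_altman(
            occ["numerical"], occ["single_step"]
        )

    kruskal = {}
    if len(subject_results) >= 2:
        kruskal["occupancy"] = kruskal_wallis([occ[m] for m in ALL_METHODS])
        kruskal["v_nd"] = kruskal_wallis([vnd[m] for m in ALL_METHODS])

    bundle = ResultsBundle(
        records=records,
        subject_results=subject_results,
        emax=emax,
        f_tests=f_tests,
        bland_altman=ba,
        kruskal=kruskal,
        exposures=exposures,
        log=log,
        errors=errors,
        seed=opts.seed,
    )
    if output_dir:
        bundle.save(output_dir)
    return bundle


# ---------------------------------------------------------------------------
# on-disk layout: one directory per subject + a study manifest


def write_study(dataset: StudyDataset, directory) -> None:
    """Persist a synthetic study as the table dialects the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    drug_series = []
    for s in dataset.subjects:
        t = s.truth
        sub = directory / t.subject
        sub.mkdir(exist_ok=True)
        write_tac_table(sub / "displacement_tacs.csv", s.displacement_tacs)
        write_tac_table(sub / "block_tacs.csv", s.block_tacs)
        write_blood_table(sub / "displacement_blood.csv", s.displacement_blood)
        write_blood_table(sub / "block_blood.csv", s.block_blood)
        write_autosampler_table(sub / "displacement_autosampler.csv", s.displacement_auto)
        write_autosampler_table(sub / "block_autosampler.csv", s.block_auto)
        drug_series += [s.drug_displacement, s.drug_block]
        meta.append(
            {
                "subject": t.subject,
                "t_b": t.t_b,
                "dose_mg_kg": t.dose_mg_kg,
                "weight_kg": t.weight_kg,
                "same_day": t.same_day,
            }
        )
    write_drug_table(directory / "drug_concentrations.csv", drug_series)
    pd.DataFrame(meta).to_csv(directory / "subjects.csv", index=False)
    dataset.manifest().to_csv(directory / "truth_manifest.csv", index=False)


def load_study(directory) -> list[SubjectInputs]:
    """Load a study directory written by :func:`write_study`."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "subjects.csv")
    drug = {(s.subject, s.scan): s for s in read_drug_table(directory / "drug_concentrations.csv")}
    out = []
    for row in meta.itertuples():
        sub = directory / str(row.subject)
        out.append(
            SubjectInputs(
                subject=str(row.subject),
                t_b=float(row.t_b),
                dose_mg_kg=float(row.dose_mg_kg),
                weight_kg=float(row.weight_kg),
                same_day=bool(row.same_day),
                displacement_tacs=read_tac_table(sub / "displacement_tacs.csv"),
                displacement_blood=read_blood_table(sub / "displacement_blood.csv"),
                displacement_auto=read_autosampler_table(sub / "displacement_autosampler.csv"),
                block_tacs=read_tac_table(sub / "block_tacs.csv"),
                block_blood=read_blood_table(sub / "block_blood.csv"),
                block_auto=read_autosampler_table(sub / "block_autosampler.csv"),
                drug_displacement=drug[(str(row.subject), "displacement")],
                drug_block=drug[(str(row.subject), "block")],
            )
        )
    return out
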