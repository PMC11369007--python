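"""Delimited-table readers/writers for all study inputs and outputs.

Files use seconds and kBq/mL (drug tables use minutes and ug/mL);
in-memory objects use minutes throughout.  Comma is the default
delimiter and tab is accepted.  Extra columns are preserved on read and
ignored; missing required columns raise with the column named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import AutosamplerSeries, BloodSampleSet
from .exposure import PlasmaDrugSeries
from .frames import FrameSchedule, TimeActivityCurve
from .lassen import OccupancyRecord

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_blood_table",
    "write_blood_table",
    "read_autosampler_table",
    "write_autosampler_table",
    "read_drug_table",
    "write_drug_table",
    "occupancy_records_frame",
    "write_occupancy_records",
    "write_json_report",
]

_FLOAT_FMT = "%.10g"


def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{Path(path).name}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read regional TACs (columns region, frame_start_s, frame_end_s,
    activity_kBq_per_mL)."""
    df = _read_table(path, ["region", "frame_start_s", "frame_end_s",
                            "activity_kBq_per_mL"])
    out = []
    for region, g in df.groupby("region", sort=False):
        g = g.sort_values("frame_start_s")
        sched = FrameSchedule.from_seconds(
            g["frame_start_s"].to_numpy(float), g["frame_end_s"].to_numpy(float)
        )
        out.append(
            TimeActivityCurve(str(region), sched, g["activity_kBq_per_mL"].to_numpy(float))
        )
    return out


def write_tac_table(path, tacs, sep: str = ",") -> None:
    frames = []
    for tac in tacs:
        frames.append(
            pd.DataFrame(
                {
                    "region": tac.region,
                    "frame_start_s": tac.schedule.start * 60.0,
                    "frame_end_s": tac.schedule.end * 60.0,
                    "activity_kBq_per_mL": tac.activity,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_blood_table(path) -> BloodSampleSet:
    """Read manual blood samples (columns time_s, whole_blood_kBq_mL,
    plasma_kBq_mL and optional parent_fraction)."""
    df = _read_table(path, ["time_s", "whole_blood_kBq_mL", "plasma_kBq_mL"])
    pf = df["parent_fraction"].to_numpy(float) if "parent_fraction" in df else None
    return BloodSampleSet(
        df["time_s"].to_numpy(float) / 60.0,
        df["whole_blood_kBq_mL"].to_numpy(float),
        df["plasma_kBq_mL"].to_numpy(float),
        pf,
    )


def write_blood_table(path, blood: BloodSampleSet, sep: str = ",") -> None:
    data = {
        "time_s": blood.time_min * 60.0,
        "whole_blood_kBq_mL": blood.whole_blood,
        "plasma_kBq_mL": blood.plasma,
    }
    if blood.parent_fraction is not None:
        data["parent_fraction"] = blood.parent_fraction
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_autosampler_table(path, background: float = 0.0) -> AutosamplerSeries:
    df = _read_table(path, ["time_s", "counts"])
    bg = float(df["background"].iloc[0]) if "background" in df else background
    return AutosamplerSeries(
        df["time_s"].to_numpy(float), df["counts"].to_numpy(float), bg
    )


def write_autosampler_table(path, auto: AutosamplerSeries, sep: str = ",") -> None:
    pd.DataFrame(
        {"time_s": auto.time_s, "counts": auto.counts, "background": auto.background}
    ).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_drug_table(path) -> list[PlasmaDrugSeries]:
    """Read plasma drug concentrations (columns subject, scan, time_min,
    conc_ug_mL); one series per (subject, scan)."""
    df = _read_table(path, ["subject", "scan", "time_min", "conc_ug_mL"])
    out = []
    for (subject, scan), g in df.groupby(["subject", "scan"], sort=False):
        g = g.sort_values("time_min")
        out.append(
            PlasmaDrugSeries(
                g["time_min"].to_numpy(float),
                g["conc_ug_mL"].to_numpy(float),
                subject=str(subject),
                scan=str(scan),
            )
        )
    return out


def write_drug_table(path, series_list, sep: str = ",") -> None:
    frames = [
        pd.DataFrame(
            {
                "subject": s.subject,
                "scan": s.scan,
                "time_min": s.time_min,
                "conc_ug_mL": s.concentration,
            }
        )
        for s in series_list
    ]
    pd.concat(frames).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def occupancy_records_frame(records: list[OccupancyRecord]) -> pd.DataFrame:
    """Tabulate occupancy records in the per-subject result-table layout."""
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "method": r.method,
                "occupancy_percent": r.occupancy_percent,
                "v_nd": r.v_nd,
                "timing_min": r.timing_min,
                "dose_mg_kg": r.dose_mg_kg,
                "converged": r.converged,
            }
            for r in records
        ]
    )


def write_occupancy_records(path, records, sep: str = ",") -> None:
    occupancy_records_frame(records).to_csv(
        path, sep=sep, index=False, float_format=_FLOAT_FMT
    )


def write_json_report(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
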