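"""Reference per-subject results of the human levetiracetam displacement study.

Eleven healthy adults each underwent two 120-min [11C]UCB-J PET scans:
a displacement scan (levetiracetam infused ~60 min after tracer
injection) and a block scan (levetiracetam given ~2 h before injection).
The published per-subject SV2A occupancy and V_ND estimates from the two
displacement-model solutions and the Lassen plot, and the total/average
AUC of the plasma levetiracetam concentration for both scans, are
transcribed here.  They serve as the worked example for the
exposure-response and agreement stages: feeding these values through
:class:`~petdisplace.exposure.EmaxModel` and
:func:`~petdisplace.agreement.bland_altman` reproduces the study's
headline Emax/IC50/R2 and coefficient-of-variation results.

Subjects flagged ``same_day`` had both scans on one day; the rest were
scanned on two separate days with identical drug doses.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reported_occupancy", "reported_exposure", "SAME_DAY_SUBJECTS"]

#: Subjects scanned twice on the same day.
SAME_DAY_SUBJECTS = (1, 2, 6, 7, 11)

_OCCUPANCY_ROWS = [
    # subject, dose mg/kg, numerical: occ% vnd te | single-step: occ% vnd ts | lassen: occ% vnd
    (1, 18, 91.4, 4.68, 6.0, 88.9, 3.83, 9.3, 88.0, 4.93),
    (2, 30, 87.9, 4.24, 12.4, 82.8, 3.36, 7.5, 87.9, 2.09),
    (3, 27, 95.8, 6.62, 23.7, 85.5, 5.95, 13.2, 83.4, 2.28),
    (4, 24, 81.2, 2.78, 15.5, 75.5, 1.94, 9.8, 92.1, 0.77),
    (5, 30, 83.5, 3.55, 15.1, 81.6, 3.21, 9.7, 86.7, 1.78),
    (6, 15, 63.0, 2.89, 16.1, 61.0, 2.67, 9.4, 61.7, 2.93),
    (7, 10, 57.7, 2.66, 14.6, 57.0, 2.62, 7.4, 61.2, 3.84),
    (8, 12, 76.5, 6.54, 21.0, 71.7, 6.02, 11.7, 69.6, 2.43),
    (9, 7, 55.0, 2.77, 22.5, 54.9, 2.94, 5.5, 30.5, 3.18),
    (10, 5, 56.9, 5.03, 43.0, 46.4, 7.43, 6.0, 69.3, 4.18),
    (11, 13, 66.8, 4.54, 24.5, 60.1, 3.81, 12.2, 76.3, 3.40),
]

_EXPOSURE_ROWS = [
    # subject, dose mg/kg, displacement total/average AUC, block total/average AUC
    (1, 18, 2123.0, 33.0, 1545.0, 13.0),
    (2, 30, 4197.0, 65.0, 3504.0, 30.0),
    (3, 27, 3620.0, 56.0, 3479.0, 30.0),
    (4, 24, 4434.0, 68.0, 4504.0, 39.0),
    (5, 30, 4401.0, 68.0, 5230.0, 45.0),
    (6, 15, 2075.0, 32.0, 2179.0, 19.0),
    (7, 10, 1041.0, 16.0, 1223.0, 11.0),
    (8, 12, 1863.0, 29.0, 1821.0, 16.0),
    (9, 7, 1289.0, 20.0, 1198.0, 10.0),
    (10, 5, 735.0, 11.0, 773.0, 7.0),
    (11, 13, 1842.0, 28.0, 1593.0, 14.0),
]


def reported_occupancy() -> pd.DataFrame:
    """Published per-subject occupancy estimates of the three methods.

    Columns: ``subject``, ``same_day``, ``dose_mg_kg``, then per method
    the occupancy (%), V_ND (mL/cm3) and, for the displacement-model
    solutions, the fitted timing parameter (``te_min`` / ``ts_min``,
    minutes after drug administration).
    """
    df = pd.DataFrame(
        _OCCUPANCY_ROWS,
        columns=[
            "subject", "dose_mg_kg",
            "occ_numerical", "vnd_numerical", "te_min",
            "occ_single_step", "vnd_single_step", "ts_min",
            "occ_lassen", "vnd_lassen",
        ],
    )
    df.insert(1, "same_day", df["subject"].isin(SAME_DAY_SUBJECTS))
    return df


def reported_exposure() -> pd.DataFrame:
    """Published per-subject plasma levetiracetam exposures for both scans.

    Columns: ``subject``, ``same_day``, ``dose_mg_kg``,
    ``total_auc_displacement`` / ``avg_auc_displacement`` (ug*min/mL and
    ug/mL over the displacement scan's post-intervention window, ~60 min)
    and ``total_auc_block`` / ``avg_auc_block`` (over the full ~120-min
    block scan).
    """
    df = pd.DataFrame(
        _EXPOSURE_ROWS,
        columns=[
            "subject", "dose_mg_kg",
            "total_auc_displacement", "avg_auc_displacement",
            "total_auc_block", "avg_auc_block",
        ],
    )
    df.insert(1, "same_day", df["subject"].isin(SAME_DAY_SUBJECTS))
    return df
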