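"""Baseline/block occupancy estimation via the Lassen plot.

Across regions with a common non-displaceable distribution volume and
uniform drug occupancy, the drop in total distribution volume obeys

    V_T(baseline) - V_T(drug) = occupancy * (V_T(baseline) - V_ND),

so regressing y = V_T(baseline) - V_T(drug) on x = V_T(baseline) gives
the occupancy as the slope and V_ND as the x-intercept.  Ordinary least
squares is used, the standard Lassen procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinetics import DisplacementResults, OneTissueModel

__all__ = [
    "LassenPlot",
    "LassenResults",
    "OccupancyRecord",
    "lassen_plot",
    "occupancy_from_displacement",
    "baseline_vt",
]


@dataclass(frozen=True)
class LassenResults:
    """OLS Lassen-plot estimates: occupancy = slope, V_ND = x-intercept."""

    occupancy: float
    v_nd: float
    slope_se: float
    intercept_se: float
    v_nd_se: float
    r_squared: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    reliable: bool = True

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * self.occupancy

    def summary(self) -> str:
        flag = "" if self.reliable else "  [V_ND UNRELIABLE: slope <= 0]"
        return (
            f"Lassen plot ({self.x.size} regions): "
            f"occupancy = {self.occupancy_percent:.1f} % (SE {100 * self.slope_se:.1f}), "
            f"V_ND = {self.v_nd:.3f} mL/cm3 (SE {self.v_nd_se:.3f}), "
            f"R2 = {self.r_squared:.3f}{flag}"
        )

    def plot(self, ax=None):
        """Scatter the per-region points with the fitted Lassen line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.x, self.y, color="k", zorder=3)
        xs = np.linspace(min(self.v_nd, self.x.min()) * 0.9, self.x.max() * 1.05, 50)
        ax.plot(xs, self.occupancy * (xs - self.v_nd), "C0-")
        ax.axhline(0, color="0.6", lw=0.8)
        ax.set_xlabel(r"$V_T$ baseline (mL/cm$^3$)")
        ax.set_ylabel(r"$V_T$ baseline $-$ $V_T$ drug (mL/cm$^3$)")
        ax.set_title(
            f"occupancy {self.occupancy_percent:.1f} %, "
            f"$V_{{ND}}$ {self.v_nd:.2f}"
        )
        return ax


class LassenPlot:
    """Lassen-plot model from matched per-region baseline and drug V_T values."""

    def __init__(self, vt_baseline, vt_drug, regions=None) -> None:
        xb = np.atleast_1d(np.asarray(vt_baseline, float))
        xd = np.atleast_1d(np.asarray(vt_drug, float))
        if xb.size != xd.size:
            raise ValueError("baseline and drug V_T arrays must have equal length")
        if xb.size < 2:
            raise ValueError("at least 2 regions are required")
        if np.ptp(xb) == 0:
            raise ValueError("baseline V_T values must not all be identical")
        self.vt_baseline = xb
        self.vt_drug = xd
        self.regions = list(regions) if regions is not None else None

    def fit(self) -> LassenResults:
        x = self.vt_baseline
        y = x - self.vt_drug
        reg = stats.linregress(x, y)
        slope, intercept = float(reg.slope), float(reg.intercept)
        reliable = slope > 0
        v_nd = -intercept / slope if reliable else float("nan")
        # delta method for the x-intercept; Cov(m, b) = -xbar * Var(m) in OLS
        var_m = reg.stderr**2
        var_b = reg.intercept_stderr**2
        cov_mb = -float(np.mean(x)) * var_m
        if reliable:
            g = np.array([intercept / slope**2, -1.0 / slope])  # d(-b/m)/d(m,b)
            v_nd_var = (
                g[0] ** 2 * var_m + g[1] ** 2 * var_b + 2 * g[0] * g[1] * cov_mb
            )
            v_nd_se = float(np.sqrt(max(v_nd_var, 0.0)))
        else:
            v_nd_se = float("nan")
        return LassenResults(
            occupancy=slope,
            v_nd=float(v_nd),
            slope_se=float(reg.stderr),
            intercept_se=float(reg.intercept_stderr),
            v_nd_se=v_nd_se,
            r_squared=float(reg.rvalue**2),
            x=x,
            y=y,
            reliable=reliable,
        )


def lassen_plot(vt_baseline, vt_drug, regions=None) -> LassenResults:
    """OLS Lassen plot of per-region baseline vs drug V_T (functional wrapper)."""
    return LassenPlot(vt_baseline, vt_drug, regions).fit()


@dataclass(frozen=True)
class OccupancyRecord:
    """One subject-by-method occupancy estimate in the common result schema."""

    subject: str
    method: str  # "numerical" | "single_step" | "lassen"
    occupancy_percent: float
    v_nd: float
    timing_min: float | None = None  # t_e or t_s (displacement methods only)
    dose_mg_kg: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy_percent <= 100.0):
            raise ValueError("occupancy % must lie in [0, 100]")
        if self.method in ("numerical", "single_step"):
            if self.timing_min is None:
                raise ValueError(f"{self.method} records require the timing parameter")
        elif self.method == "lassen":
            if self.timing_min is not None:
                raise ValueError("lassen records carry no timing parameter")
        else:
            raise ValueError(f"unknown method {self.method!r}")


def occupancy_from_displacement(
    fit: DisplacementResults,
    subject: str = "",
    dose_mg_kg: float | None = None,
) -> OccupancyRecord:
    """Repackage a displacement fit as an :class:`OccupancyRecord`."""
    return OccupancyRecord(
        subject=subject,
        method=fit.solution,
        occupancy_percent=fit.occupancy_percent,
        v_nd=fit.v_nd,
        timing_min=fit.timing,
        dose_mg_kg=dose_mg_kg,
        converged=fit.converged,
    )


def baseline_vt(
    tacs,
    input_fn,
    t_intervention: float,
    weights="decay",
    min_segment_min: float = 30.0,
    dt=None,
) -> dict[str, float]:
    """Per-region baseline V_T from the pre-drug segment of a displacement scan.

    Fits the standard 1TCM to each region using only frames that end at
    or before the recorded intervention time.
    """
    from .kinetics import DEFAULT_FIT_DT_MIN

    if t_intervention < min_segment_min:
        raise ValueError(
            f"intervention at {t_intervention} min leaves less than the "
            f"configured minimum {min_segment_min}-min baseline segment"
        )
    dt = DEFAULT_FIT_DT_MIN if dt is None else dt
    out = {}
    for tac in tacs:
        res = OneTissueModel(
            tac, input_fn, weights=weights, t_max=t_intervention, dt=dt
        ).fit()
        out[tac.region] = res.params.vt
    return out
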