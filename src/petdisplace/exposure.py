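"""Drug-exposure summaries (AUC) and the Emax exposure-occupancy model.

Exposure X is the area under the plasma drug concentration-time curve
(trapezoidal rule), reported both as the total AUC (ug*min/mL) and
normalized by the sampling duration (average AUC, ug/mL).  Occupancy Y
relates to exposure through the single-site binding (Emax) model

    Y = Emax * X / (IC50 + X),

fitted by unweighted nonlinear least squares either with Emax free
(two-parameter) or fixed at 100 % (one-parameter); the nested pair is
compared with the extra-sum-of-squares F test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "PlasmaDrugSeries",
    "ExposureSummary",
    "EmaxModel",
    "EmaxResults",
    "FTestResult",
    "compute_auc",
    "fit_emax",
    "extra_ss_f_test",
]


@dataclass(frozen=True)
class PlasmaDrugSeries:
    """Plasma drug concentration samples (ug/mL) over time (minutes)."""

    time_min: np.ndarray
    concentration: np.ndarray
    subject: str = ""
    scan: str = "displacement"  # "displacement" | "block"

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.time_min, float))
        c = np.atleast_1d(np.asarray(self.concentration, float))
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "concentration", c)
        if t.size != c.size or t.size == 0:
            raise ValueError("time and concentration must have equal nonzero length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.scan not in ("displacement", "block"):
            raise ValueError("scan must be 'displacement' or 'block'")


@dataclass(frozen=True)
class ExposureSummary:
    """Total AUC (ug*min/mL), window duration (min) and average AUC (ug/mL)."""

    total_auc: float
    duration: float
    average_auc: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not np.isclose(self.average_auc * self.duration, self.total_auc, rtol=1e-6):
            raise ValueError("average_auc * duration must equal total_auc")


def compute_auc(
    series: PlasmaDrugSeries, t_start: float, t_end: float
) -> ExposureSummary:
    """Trapezoidal AUC of the concentration curve over [t_start, t_end].

    Window endpoints falling between samples are included by linear
    interpolation; outside the sampled range the edge concentration is
    held constant.  Requires at least 2 samples inside the window
    (endpoints included).
    """
    if not t_start < t_end:
        raise ValueError("t_start must be earlier than t_end")
    t, c = series.time_min, series.concentration
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate([[t_start], t[inside], [t_end]])
    cc = np.interp(tt, t, c)
    if tt.size < 2:
        raise ValueError("empty exposure window")
    total = float(np.trapezoid(cc, tt))
    duration = float(t_end - t_start)
    return ExposureSummary(total, duration, total / duration)


@dataclass(frozen=True)
class FTestResult:
    """Extra-sum-of-squares F test of nested least-squares fits."""

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


@dataclass
class EmaxResults:
    """Emax-fit results: estimates, Wald CIs, fit quality, nesting info."""

    emax: float
    ic50: float
    emax_fixed: bool
    ssr: float
    df: int
    r_squared: float
    bse: dict[str, float]
    cov: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def n_obs(self) -> int:
        return self.x.size

    @property
    def n_params(self) -> int:
        return 1 if self.emax_fixed else 2

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return self.emax * x / (self.ic50 + x)

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Asymptotic (Wald, t-based) confidence intervals of the free parameters."""
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df)
        out = {"ic50": (self.ic50 - tcrit * self.bse["ic50"],
                        self.ic50 + tcrit * self.bse["ic50"])}
        if not self.emax_fixed:
            out["emax"] = (self.emax - tcrit * self.bse["emax"],
                           self.emax + tcrit * self.bse["emax"])
        return out

    def bootstrap_conf_int(
        self, alpha: float = 0.05, n_boot: int = 2000, seed: int = 0
    ) -> dict[str, tuple[float, float]]:
        """Percentile bootstrap CIs (case resampling, seeded).

        Printed CIs of this kind of analysis are often asymmetric; the
        bootstrap accommodates that where the Wald interval cannot.
        """
        rng = np.random.default_rng(seed)
        n = self.n_obs
        em, ic = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.ptp(self.x[idx]) == 0:
                continue
            try:
                r = EmaxModel(self.x[idx], self.y[idx]).fit(fix_emax=self.emax_fixed)
            except (ValueError, RuntimeError):
                continue
            em.append(r.emax)
            ic.append(r.ic50)
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        out = {"ic50": tuple(np.percentile(ic, [lo, hi]))}
        if not self.emax_fixed:
            out["emax"] = tuple(np.percentile(em, [lo, hi]))
        return out

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Emax model ({'1' if self.emax_fixed else '2'}-parameter), "
            f"n = {self.n_obs}",
            f"  Emax = {self.emax:7.2f} %"
            + ("  [fixed]" if self.emax_fixed
               else f"  (95% CI {ci['emax'][0]:.0f}-{ci['emax'][1]:.0f})"),
            f"  IC50 = {self.ic50:7.3f}   (95% CI {ci['ic50'][0]:.2f}-{ci['ic50'][1]:.2f})",
            f"  R2 = {self.r_squared:.3f}   SSR = {self.ssr:.4g}   df = {self.df}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, label=None):
        """Scatter of the exposure-occupancy points with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.x, self.y, zorder=3, label=label)
        xs = np.linspace(0.0, self.x.max() * 1.1, 200)
        ax.plot(xs, self.predict(xs))
        ax.set_xlabel("plasma drug exposure X (AUC)")
        ax.set_ylabel("occupancy (%)")
        return ax


class EmaxModel:
    """Single-site binding model of occupancy (%) against exposure.

    Parameters
    ----------
    x : array
        Exposures (total or average AUC); must be positive.
    y : array
        Occupancies, percent.
    """

    def __init__(self, x, y) -> None:
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if np.any(x <= 0):
            raise ValueError("exposures must be positive")
        if np.ptp(y) == 0:
            raise ValueError("degenerate input: all occupancies identical")
        self.x, self.y = x, y

    def fit(self, fix_emax: bool = False) -> EmaxResults:
        """Unweighted nonlinear least squares; ``fix_emax`` pins Emax at 100 %."""
        x, y = self.x, self.y
        n = x.size
        k = 1 if fix_emax else 2
        if n < k + 1:
            raise ValueError(f"need at least {k + 1} points for a {k}-parameter fit")

        ic50_0 = float(np.median(x))
        if fix_emax:
            def resid(p):
                return 100.0 * x / (p[0] + x) - y
            p0, lo, hi = [ic50_0], [1e-9], [np.inf]
        else:
            def resid(p):
                return p[0] * x / (p[1] + x) - y
            p0, lo, hi = [max(float(y.max()), 1.0), ic50_0], [0.0, 1e-9], [np.inf, np.inf]

        res = least_squares(resid, p0, bounds=(lo, hi), ftol=1e-14, xtol=1e-14,
                            gtol=1e-14, max_nfev=20000)
        if not res.success:
            raise RuntimeError("Emax fit did not converge")
        ssr = float(2.0 * res.cost)
        df = n - k
        sstot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ssr / sstot if sstot > 0 else float("nan")
        s2 = ssr / max(df, 1)
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if fix_emax:
            emax, ic50 = 100.0, float(res.x[0])
            bse = {"ic50": float(se[0])}
        else:
            emax, ic50 = float(res.x[0]), float(res.x[1])
            bse = {"emax": float(se[0]), "ic50": float(se[1])}
        return EmaxResults(
            emax=emax, ic50=ic50, emax_fixed=fix_emax, ssr=ssr, df=df,
            r_squared=r2, bse=bse, cov=cov, x=x, y=y, converged=True,
        )


def fit_emax(exposures, occupancies, fix_emax_100: bool = False) -> EmaxResults:
    """Fit the Emax model to exposure-occupancy pairs (functional wrapper)."""
    return EmaxModel(exposures, occupancies).fit(fix_emax=fix_emax_100)


def extra_ss_f_test(nested: EmaxResults, full: EmaxResults) -> FTestResult:
    """Extra-sum-of-squares F test of a nested (fewer-parameter) vs full fit.

    F = ((SS_n - SS_f) / (df_n - df_f)) / (SS_f / df_f), with the p-value
    from the F(df_n - df_f, df_f) distribution.
    """
    if nested.n_obs != full.n_obs:
        raise ValueError("both fits must use the same data")
    if not np.array_equal(nested.x, full.x) or not np.array_equal(nested.y, full.y):
        raise ValueError("both fits must use the same data")
    if nested.df <= full.df:
        raise ValueError("nested fit must have more residual degrees of freedom")
    if full.ssr == 0.0:
        if nested.ssr > 0.0:
            raise ZeroDivisionError(
                "full model fits exactly while nested does not; F undefined"
            )
        return FTestResult(0.0, 1.0, nested.df - full.df, full.df)
    df_num = nested.df - full.df
    df_den = full.df
    f = max((nested.ssr - full.ssr) / df_num, 0.0) / (full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return FTestResult(float(f), p, df_num, df_den)
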