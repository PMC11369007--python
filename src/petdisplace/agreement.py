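"""Method-agreement and group-comparison statistics.

Bland-Altman analysis of paired occupancy estimates (bias, limits of
agreement, and a coefficient of variation defined as the SD of the
between-method differences over the mean of all measurements), plus thin
wrappers for the Kruskal-Wallis rank test and the pooled two-sample
t-test with Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "kruskal_wallis",
    "two_sample_t_cohens_d",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman agreement between two paired measurement methods.

    ``cv_percent`` uses the grand mean of all 2n measurements in the
    denominator; ``cv_pair_means_percent`` uses the mean of the per-pair
    means (identical for complete paired data, both reported).
    Differences are signed (a - b): the standard Bland-Altman quantity,
    and the only one under which limits of agreement are meaningful.
    """

    means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)
    bias: float
    sd_differences: float
    lower_loa: float
    upper_loa: float
    cv_percent: float
    cv_pair_means_percent: float
    fraction_within_loa: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.means, self.differences, color="k", zorder=3)
        for y, style in [(self.bias, "-"), (self.lower_loa, "--"), (self.upper_loa, "--")]:
            ax.axhline(y, color="C0", linestyle=style, lw=1)
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (a - b)")
        ax.set_title(f"bias {self.bias:.2f}, CV {self.cv_percent:.1f} %")
        return ax


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman comparison of two equal-length paired measurement arrays."""
    a = np.atleast_1d(np.asarray(a, float))
    b = np.atleast_1d(np.asarray(b, float))
    if a.size != b.size:
        raise ValueError("paired arrays must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    means = 0.5 * (a + b)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = bias - 1.96 * sd, bias + 1.96 * sd
    grand_mean = float(np.concatenate([a, b]).mean())
    cv = 100.0 * sd / grand_mean if grand_mean != 0 else float("inf")
    cv_pm = 100.0 * sd / float(means.mean()) if means.mean() != 0 else float("inf")
    within = float(np.mean((d >= lower) & (d <= upper)))
    return BlandAltmanResult(
        means=means,
        differences=d,
        bias=bias,
        sd_differences=sd,
        lower_loa=float(lower),
        upper_loa=float(upper),
        cv_percent=float(cv),
        cv_pair_means_percent=float(cv_pm),
        fraction_within_loa=within,
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups; returns (H, p).

    Rank-based with tie correction; p from the chi-square approximation.
    Identical groups give H = 0, p = 1.
    """
    groups = [np.atleast_1d(np.asarray(g, float)) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # scipy raises on all-identical data
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def two_sample_t_cohens_d(x, y) -> tuple[float, float, float]:
    """Pooled-variance two-sample t test plus Cohen's d; returns (t, p, d)."""
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ZeroDivisionError("zero pooled variance")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return float(t), float(p), float(d)
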