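"""Arterial blood processing: building the metabolite-corrected input function.

The plasma input function C_p(t) that drives the kinetic models is
assembled from three ingredients:

1. manual arterial samples (whole-blood and plasma activity, and the
   fraction of plasma activity attributable to unmetabolized parent
   tracer, measured by radio-HPLC on a subset of samples);
2. an optional continuous autosampler whole-blood series (1 Hz for the
   first ~10 min), background-subtracted, decay-corrected and
   cross-calibrated against the overlapping manual samples by a single
   multiplicative factor;
3. a monotone-nonincreasing sigmoid parent-fraction model
   ``pf(t) = 1 - (1 - b) * t**n / (t**n + c**n)`` with ``pf(0) = 1``.

Curves are interpolated piecewise-linearly between samples and
extrapolated beyond the last sample with a single exponential fitted to
the last three samples.  Activities are kBq/mL, times minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "C11_HALF_LIFE_MIN",
    "BloodSampleSet",
    "AutosamplerSeries",
    "ParentFractionModel",
    "CalibrationResult",
    "InputFunction",
    "decay_correct",
    "decay_uncorrect",
    "calibrate_autosampler",
    "fit_parent_fraction",
    "build_input_function",
]

#: Physical half-life of carbon-11, minutes.
C11_HALF_LIFE_MIN = 20.364


def decay_correct(activity, t_min, half_life: float = C11_HALF_LIFE_MIN):
    """Correct measured activity at time ``t_min`` back to injection time.

    Returns ``activity * 2**(t/half_life)``. Negative times are rejected
    (all values are referenced to injection = time zero).
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative sample times are not allowed")
    out = np.asarray(activity, dtype=float) * 2.0 ** (t / half_life)
    return float(out) if out.ndim == 0 else out


def decay_uncorrect(activity, t_min, half_life: float = C11_HALF_LIFE_MIN):
    """Inverse of :func:`decay_correct` (physical decay applied forward)."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative sample times are not allowed")
    out = np.asarray(activity, dtype=float) * 2.0 ** (-t / half_life)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BloodSampleSet:
    """Manual arterial samples: whole-blood/plasma activity and parent fraction.

    ``parent_fraction`` may be NaN where no metabolite measurement exists.
    All activities are decay-corrected to injection time.
    """

    time_min: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.time_min, float))
        wb = np.atleast_1d(np.asarray(self.whole_blood, float))
        pl = np.atleast_1d(np.asarray(self.plasma, float))
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "whole_blood", wb)
        object.__setattr__(self, "plasma", pl)
        if not (t.size == wb.size == pl.size) or t.size == 0:
            raise ValueError("time, whole_blood and plasma must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("sample times must be nonnegative")
        if np.any(wb < 0) or np.any(pl < 0):
            raise ValueError("activities must be nonnegative")
        if self.parent_fraction is not None:
            pf = np.atleast_1d(np.asarray(self.parent_fraction, float))
            object.__setattr__(self, "parent_fraction", pf)
            if pf.size != t.size:
                raise ValueError("parent_fraction length mismatch")
            ok = np.isfinite(pf)
            if np.any((pf[ok] < 0) | (pf[ok] > 1)):
                raise ValueError("parent fractions must lie in [0, 1]")

    def sorted_copy(self) -> "BloodSampleSet":
        return self  # construction already enforces order

    @classmethod
    def from_unordered(cls, time_min, whole_blood, plasma, parent_fraction=None):
        """Build from samples in arbitrary order (sorts by time)."""
        t = np.atleast_1d(np.asarray(time_min, float))
        order = np.argsort(t)
        pf = None
        if parent_fraction is not None:
            pf = np.atleast_1d(np.asarray(parent_fraction, float))[order]
        return cls(
            t[order],
            np.atleast_1d(np.asarray(whole_blood, float))[order],
            np.atleast_1d(np.asarray(plasma, float))[order],
            pf,
        )


@dataclass(frozen=True)
class AutosamplerSeries:
    """Continuous (1 Hz) whole-blood detector counts with a background level.

    ``time_s`` must be uniformly spaced. Counts are raw (not decay
    corrected); ``background`` is subtracted and the result clamped at 0.
    """

    time_s: np.ndarray
    counts: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.time_s, float))
        c = np.atleast_1d(np.asarray(self.counts, float))
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "counts", c)
        if t.size != c.size or t.size < 2:
            raise ValueError("time_s and counts must have equal length >= 2")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9) or steps[0] <= 0:
            raise ValueError("autosampler sampling must be uniform and increasing")

    @property
    def net_counts(self) -> np.ndarray:
        """Background-subtracted counts, clamped at zero."""
        return np.clip(self.counts - self.background, 0.0, None)

    @property
    def time_min(self) -> np.ndarray:
        return self.time_s / 60.0


@dataclass(frozen=True)
class ParentFractionModel:
    """Sigmoid parent-fraction model pf(t) = 1 - (1-b) t^n / (t^n + c^n).

    ``b`` is the asymptotic parent fraction, ``c`` the half-conversion
    time (minutes) and ``n`` the Hill slope; pf(0) = 1 and pf is
    monotone nonincreasing for b <= 1.
    """

    b: float = 0.2
    c: float = 30.0
    n: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("b must lie in [0, 1]")
        if self.c <= 0 or self.n <= 0:
            raise ValueError("c and n must be positive")

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.clip(np.asarray(t, float), 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            tn = t_arr**self.n
            frac = np.where(t_arr > 0, tn / (tn + self.c**self.n), 0.0)
        out = 1.0 - (1.0 - self.b) * frac
        return float(out) if out.ndim == 0 else out


def fit_parent_fraction(samples: BloodSampleSet) -> ParentFractionModel:
    """Fit the sigmoid parent-fraction model to measured parent fractions.

    Requires at least 3 samples with a finite parent fraction.
    """
    if samples.parent_fraction is None:
        raise ValueError("samples carry no parent-fraction measurements")
    ok = np.isfinite(samples.parent_fraction)
    if ok.sum() < 3:
        raise ValueError("need at least 3 parent-fraction samples")
    t = samples.time_min[ok]
    pf = samples.parent_fraction[ok]
    if np.all(pf >= 1.0 - 1e-12):
        return ParentFractionModel(b=1.0, c=30.0, n=2.0)

    def model(t, b, c, n):
        return ParentFractionModel(b, c, n)(t)

    p0 = (max(float(pf.min()), 1e-3), max(float(np.median(t)), 1.0), 2.0)
    popt, _ = curve_fit(
        model, t, pf, p0=p0,
        bounds=([0.0, 1e-3, 0.1], [1.0, 1e4, 10.0]),
        maxfev=20000,
    )
    return ParentFractionModel(*[float(v) for v in popt])


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated whole-blood curve from autosampler + manual samples."""

    time_min: np.ndarray
    whole_blood: np.ndarray
    factor: float
    n_overlap: int
    residual_ss: float
    degenerate: bool = False


def calibrate_autosampler(
    auto: AutosamplerSeries,
    manual: BloodSampleSet,
    half_life: float = C11_HALF_LIFE_MIN,
    window_s: float = 10.0,
) -> CalibrationResult:
    """Scale autosampler counts to kBq/mL against overlapping manual samples.

    Background-subtracted counts are decay-corrected and scaled by a
    single multiplicative factor estimated by least squares (through the
    origin) against manual whole-blood samples falling inside the
    autosampler window; the calibrated series is then merged with the
    manual samples recorded after the window ends.  Counts are averaged
    over ``window_s`` seconds around each manual draw so single-sample
    counting noise does not propagate into the factor.
    """
    t_auto = auto.time_min
    corrected = decay_correct(auto.net_counts, t_auto, half_life)
    in_window = (manual.time_min >= t_auto[0]) & (manual.time_min <= t_auto[-1])
    n_overlap = int(in_window.sum())
    if n_overlap < 2:
        raise ValueError(
            "fewer than 2 manual samples overlap the autosampler window; "
            "use manual-only mode (build_input_function with auto=None)"
        )
    ref = manual.whole_blood[in_window]
    half_w = window_s / 120.0  # half window, minutes
    pred = np.empty(n_overlap)
    for i, tm in enumerate(manual.time_min[in_window]):
        near = np.abs(t_auto - tm) <= half_w
        pred[i] = corrected[near].mean() if near.any() else np.interp(
            tm, t_auto, corrected
        )
    denom = float(pred @ pred)
    degenerate = denom <= 0.0
    factor = 0.0 if degenerate else float(pred @ ref) / denom
    resid = ref - factor * pred
    calibrated = factor * corrected

    after = manual.time_min > t_auto[-1]
    time = np.concatenate([t_auto, manual.time_min[after]])
    wb = np.concatenate([calibrated, manual.whole_blood[after]])
    return CalibrationResult(
        time_min=time,
        whole_blood=wb,
        factor=factor,
        n_overlap=n_overlap,
        residual_ss=float(resid @ resid),
        degenerate=degenerate,
    )


def _fit_exp_tail(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Single-exponential y = A exp(-k (t - t[-1])) through the last samples.

    Log-linear least squares on the provided (tail) points; returns
    (A at last sample time, decay rate k >= 0). Falls back to a flat
    extension when values are nonpositive or increasing.
    """
    pos = y > 0
    if pos.sum() < 2:
        return float(max(y[-1], 0.0)), 0.0
    tt, yy = t[pos], y[pos]
    slope, intercept = np.polyfit(tt, np.log(yy), 1)
    k = max(-slope, 0.0)
    amp = float(np.exp(intercept + slope * t[-1]))
    return amp, float(k)


class InputFunction:
    """Metabolite-corrected arterial input: C_p (parent plasma) and whole blood.

    Both curves are defined on the whole scan interval: piecewise-linear
    between samples, linear from (0, 0) up to the first sample, and a
    fitted single-exponential tail beyond the last sample.  Evaluation at
    an exact sample time returns the sample value.
    """

    interpolation = "piecewise-linear; exponential tail from last 3 samples"

    def __init__(
        self,
        time_min,
        plasma_parent,
        whole_blood,
        *,
        tail_points: int = 3,
    ) -> None:
        t = np.atleast_1d(np.asarray(time_min, float))
        cp = np.atleast_1d(np.asarray(plasma_parent, float))
        wb = np.atleast_1d(np.asarray(whole_blood, float))
        if not (t.size == cp.size == wb.size) or t.size < 2:
            raise ValueError("need equal-length time/plasma/whole-blood arrays (n >= 2)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(cp < 0) or np.any(wb < 0):
            raise ValueError("input-function curves must be nonnegative")
        if t[0] > 0:  # anchor at injection: no tracer in blood before arrival
            t = np.concatenate([[0.0], t])
            cp = np.concatenate([[0.0], cp])
            wb = np.concatenate([[0.0], wb])
        self.time_min = t
        self.plasma_parent_samples = cp
        self.whole_blood_samples = wb
        k = min(tail_points, t.size)
        self._cp_tail = _fit_exp_tail(t[-k:], cp[-k:])
        self._wb_tail = _fit_exp_tail(t[-k:], wb[-k:])

    def _eval(self, t, samples, tail) -> np.ndarray:
        t_arr = np.asarray(t, dtype=float)
        out = np.interp(t_arr, self.time_min, samples)
        t_last = self.time_min[-1]
        beyond = t_arr > t_last
        if np.any(beyond):
            amp, k = tail
            out = np.where(beyond, amp * np.exp(-k * (t_arr - t_last)), out)
        return out

    def plasma_parent(self, t) -> np.ndarray | float:
        """C_p(t): unmetabolized-parent plasma concentration, kBq/mL."""
        out = self._eval(t, self.plasma_parent_samples, self._cp_tail)
        return float(out) if out.ndim == 0 else out

    def whole_blood(self, t) -> np.ndarray | float:
        """C_wb(t): whole-blood concentration, kBq/mL (vascular term)."""
        out = self._eval(t, self.whole_blood_samples, self._wb_tail)
        return float(out) if out.ndim == 0 else out

    def covers(self, t_end: float) -> bool:
        """Whether the sampled support reaches ``t_end`` (tail excluded)."""
        return self.time_min[-1] >= t_end - 1e-9


def build_input_function(
    blood: BloodSampleSet,
    auto: AutosamplerSeries | None = None,
    pf_model: ParentFractionModel | None = None,
    *,
    max_gap_min: float = 45.0,
    half_life: float = C11_HALF_LIFE_MIN,
) -> InputFunction:
    """Assemble the metabolite-corrected input function from blood data.

    C_p(t) is the plasma-activity interpolant multiplied by the parent
    fraction pf(t); the whole-blood curve comes from the calibrated
    autosampler/manual merge (or manual samples alone).  Plasma activity
    at autosampler-only time points uses the nearest known
    plasma-to-whole-blood ratio (carried forward/backward).

    Raises if the sample coverage has a gap larger than ``max_gap_min``.
    """
    if pf_model is None:
        pf_model = (
            fit_parent_fraction(blood)
            if blood.parent_fraction is not None
            and np.isfinite(blood.parent_fraction).sum() >= 3
            else ParentFractionModel()
        )

    if auto is not None:
        cal = calibrate_autosampler(auto, blood, half_life)
        wb_time, wb_vals = cal.time_min, cal.whole_blood
    else:
        wb_time, wb_vals = blood.time_min, blood.whole_blood

    gaps = np.diff(np.concatenate([[0.0], blood.time_min]))
    if np.any(gaps > max_gap_min):
        raise ValueError(
            f"plasma sample coverage gap of {gaps.max():.1f} min exceeds "
            f"the configured maximum of {max_gap_min} min"
        )

    # plasma total activity on the merged whole-blood time base, via the
    # nearest measured plasma/whole-blood ratio where plasma was not drawn
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(blood.whole_blood > 0, blood.plasma / blood.whole_blood, np.nan)
    if np.all(~np.isfinite(ratio)):
        ratio_interp = np.ones_like(wb_time)
    else:
        okr = np.isfinite(ratio)
        ratio_interp = np.interp(wb_time, blood.time_min[okr], ratio[okr])
    plasma_total = np.where(
        np.isin(wb_time, blood.time_min),
        np.interp(wb_time, blood.time_min, blood.plasma),
        wb_vals * ratio_interp,
    )
    cp = plasma_total * np.asarray(pf_model(wb_time), dtype=float)
    return InputFunction(wb_time, cp, wb_vals)
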