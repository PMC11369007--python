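# Methods

## The displacement model

`petdisplace` treats a dynamic PET scan with an intra-scan drug
intervention as a one-tissue-compartment (1TC) system whose efflux rate
is modulated by the drug's target occupancy ∂(t):

    dC_T/dt = K1 C_p(t) − k2 / (1 + (1 − ∂(t)) BP_ND) · C_T(t),
    k2 = K1 / V_ND,   BP_ND = V_T / V_ND − 1.

C_p is the metabolite-corrected arterial plasma tracer concentration,
V_T the baseline total distribution volume of a region, and V_ND the
non-displaceable distribution volume shared by all regions. With ∂ ≡ 0
the system reduces exactly to the standard 1TCM (efflux K1/V_T); with
∂ ≡ 1 all specific binding is abolished and the apparent distribution
volume collapses to V_ND. Assumptions inherited from the 1TC framework:
a single well-mixed tissue compartment per region (adequate for tracers
whose 2TC micro-rates are fast), instantaneous equilibration of the
drug's effect on the efflux term, occupancy identical across regions,
and V_ND identical across regions. No plasma-to-tissue delay parameter
is fitted; a fixed delay can be applied by shifting the input function
(default 0).

Two occupancy time-courses are supported:

- **numerical ramp** — ∂(t) = ∂max (1 + 2(t_e − t)/(t_e − t_b)) ·
  ((t − t_b)/(t_e − t_b))² on [t_b, t_e], i.e. the cubic smoothstep
  ∂max(3τ² − 2τ³): zero until drug administration at t_b, smoothly
  nondecreasing, flat at both ends, ∂max from t_e on. Appropriate for
  drugs with slow brain entry.
- **single step** — ∂(t) jumps from 0 to ∂max at a fitted time
  t_s > t_b. Appropriate for fast-acting drugs; for slow drugs it
  tends to underestimate occupancy slightly.

The measured regional signal is (1 − v_B) C_T + v_B C_wb with C_wb the
whole-blood curve, and the model value of a frame is the trapezoidal
time-average of that signal over the frame interval — PET frames are
integrals, not point samples.

## Numerical integration

The ODE is propagated by forward Euler on a uniform grid, with the
input and the time-varying rate sampled at step midpoints; midpoint
sampling removes the O(dt) error constant that left-endpoint sampling
leaves in the earliest 15-s frames during the bolus peak. The
recurrence is evaluated as an exact log-space cumulative sum
(vectorized, equal to the sequential loop to rounding), renormalized in
blocks so extreme rate values visited by the optimizer cannot overflow.
Forward simulation defaults to a 0.1-s step (frame-average error vs an
adaptive LSODA reference ≤ 1e-5 relative); fitting defaults to 0.5 s
(error ≤ 1e-4, negligible against measurement noise, five times
cheaper). The discontinuous step profile enters the grid through the
fractional coverage of each step interval beyond t_s, keeping the
least-squares objective continuous in t_s; a midpoint-sampled step
would make it piecewise constant and freeze t_s at its initial value.

## Fitting

All fits are weighted nonlinear least squares (`scipy.optimize.
least_squares`, trust-region reflective). Default frame weights are
duration × exp(−λ t_mid) with λ the carbon-11 decay constant — a
standard counts-informativeness surrogate — normalized to mean 1;
uniform weights are available. The joint displacement fit estimates
3 R + 3 parameters for R regions. Bounds: K1 ∈ [1e-4, 5] mL/cm³/min,
V_T ∈ [0.5, 300] mL/cm³ (the lower bound excludes a degenerate
fast-equilibrium solution that can mimic the blood signal),
v_B ∈ [0, 0.2], V_ND ∈ [0.05, 100]. ∂max is optimized on a logit scale
and the timing offset t_e − t_b (or t_s − t_b) on a log scale, so
0 < ∂max < 1 and t_e > t_b hold by construction. Initialization: each
region's (K1, V_T, v_B) from a 1TCM fit of its pre-drug segment,
V_ND at half the smallest initial V_T, ∂max at 0.5, timing at
t_b + 10 min; three starts (the base start plus two seeded jitters)
guard against local minima. Convergence tolerances are 1e-9
(relative); a non-convergent optimizer status is reported through the
results object, never silently. Standard errors come from the Gauss–
Newton covariance s²(JᵀJ)⁻¹ at the solution, delta-transformed back to
the natural scale for ∂max and the timing parameter.

The fit surface has a known weak direction: post-drug kinetics
constrain mainly the apparent volume V_ND + (1 − ∂max)(V_T − V_ND), so
(V_ND, ∂max) are separated only by the transition window and by V_T
diversity across regions. With noisy data the pair can wander along
this ridge (occasionally to the V_ND lower bound on a single start);
multi-start resolves the collapse, and the reported standard errors are
honest about the remaining width. Occupancy estimates are unbiased over
replicates, but single-scan values carry standard errors of several
percentage points at realistic noise.

Baseline V_T for the Lassen comparator is fitted from the pre-drug
segment only (frames ending at or before the recorded intervention
time — each subject's actual time, not a fixed 60 min); block-scan V_T
uses the full 120 min. The Lassen regression is OLS (the standard
procedure; error-in-variables alternatives are out of scope), with the
V_ND x-intercept's standard error from the delta method using the OLS
slope/intercept covariance.

## Input function

C_p(t) is assembled as (total plasma activity interpolant) × pf(t),
with pf the parent fraction fitted by the monotone sigmoid
pf(t) = 1 − (1 − b) tⁿ/(tⁿ + cⁿ) (pf(0) = 1; defaults b = 0.2,
c = 30 min, n = 2 — explicit stand-ins, since the original
metabolite-analysis protocol lives in external methods). Curves are
piecewise-linear between samples, anchored at (0, 0), and extrapolated
beyond the last sample by a single exponential fitted to the last three
samples. The autosampler series is background-subtracted (clamped at
zero), decay-corrected, averaged over 10-s windows around each
overlapping manual draw, and scaled by one least-squares factor; the
calibrated curve is merged with the manual samples drawn after the
autosampler window. No dispersion correction is applied by default (the
analysis it emulates reports none). Where plasma was not drawn at a
whole-blood time point, the nearest measured plasma-to-whole-blood
ratio is carried over. Piecewise-linear interpolation of a convex
decaying plasma curve between sparse late samples carries a small
positive chord bias (~1.6 % of the integrated C_p with the standard
manual sampling times); this is inherent to the interpolation rule, not
to the assembly.

## Exposure–response and agreement statistics

Drug exposure X is the trapezoidal AUC of the plasma concentration
(window endpoints interpolated), reported as total AUC (µg·min/mL) and
as average AUC = total/duration (µg/mL). Displacement-method
occupancies pair with the displacement scan's post-intervention
exposure (~60 min window); Lassen occupancies pair with the block
scan's full-scan exposure (~120 min): each method's occupancy is
measured during that scan. Emax fits are unweighted; confidence
intervals are asymptotic (t-based Wald) by default with a seeded
case-resampling bootstrap available, since published intervals of this
kind are asymmetric. The extra-sum-of-squares F test compares the
Emax-fixed (100 %) and Emax-free fits.

Bland–Altman uses signed differences (the only convention under which
limits of agreement are meaningful); the coefficient of variation is
100 × SD(differences) / mean of all 2n measurements, with the
per-pair-means denominator also reported (identical for complete
pairs). Difference SDs use the n − 1 divisor. Kruskal–Wallis is
rank-based with tie correction and a chi-square p-value — at very small
samples (3 × 3) that approximation deviates from the exact permutation
p by up to ~0.1 near the center of the distribution, a property of the
test, not of the implementation. The two-sample t statistic uses pooled
variance, with Cohen's d = mean difference / pooled SD.

## Synthetic studies

The generator emulates the validation study design: paired 120-min
displacement and block scans on the 36-frame schedule (8×15, 8×30,
4×60, 5×120, 2×300, 9×600 s), manual arterial samples at the study's
draw times, a 1-Hz autosampler for the first 10 min, and drug doses
spread over 5–30 mg/kg with five same-day and six different-day
subjects.

- **Tracer input**: linear upslope over a 30-s bolus, then a
  tri-exponential decay of total plasma activity (peak 80 kBq/mL,
  rates 4, 0.25, 0.012 min⁻¹, weights ¼, ¼, ½); whole blood = plasma ×
  (0.75 + 0.25 e^(−t/40)); the sigmoid parent fraction above.
- **Regional kinetics**: seven regions (hippocampus, frontal cortex,
  temporal cortex, striatum, posterior cingulate, thalamus, insula)
  with K1 0.10–0.16 mL/cm³/min, V_T 12–20 mL/cm³, v_B 0.04–0.06,
  V_ND 4.0 mL/cm³, mildly jittered per subject.
- **Drug PK**: two-compartment disposition, 4-min zero-order infusion;
  central volume 0.25 L/kg, steady-state volume 0.6 L/kg, terminal
  half-life ~7 h (literature-typical stand-ins), distribution rate
  0.03 min⁻¹ calibrated once so the displacement-scan average AUC is
  ≈2.2 µg/mL per mg/kg — the scale of the published per-subject
  exposures.
- **Occupancy truth**: the displacement scan's ∂max and the block
  scan's constant occupancy both read off a configured true Emax curve
  (default Emax 100 %, IC50 12 µg/mL average-AUC scale) at the scan's
  true average exposure. The block scan's drug is given 120 min before
  injection; different-day subjects get a multiplicative between-day
  V_T perturbation (default SD 5 %) emulating test–retest variability.
- **TAC noise**: Gaussian per frame with variance ∝ signal /
  (frame duration × decay factor), parameterized as the fractional SD
  at the first 600-s frame; default 2 %. That level was chosen because
  it reproduces between-method agreement CVs in the 10–20 % range seen
  in real data; it implies ~10 % noise in the final frames, where
  carbon-11 decay has cost two half-lives.

What the generator does **not** emulate: image reconstruction and
partial-volume effects, motion, dispersion in the autosampler line,
correlated (non-Gaussian) frame noise, regional occupancy
heterogeneity, and plasma-free-fraction variability. Passing the
recovery tests therefore shows the estimators are correct and
well-calibrated under the model's own assumptions — not that those
assumptions hold in acquired data.

## Problem sizes used in the test suite

Noiseless joint-fit recovery uses one 7-region subject; the stochastic
recovery study uses 100 replicates of a 15 mg/kg subject at the default
noise level; the end-to-end study uses 11 subjects with doses spread
over 5–30 mg/kg, analyzed entirely from the generated tables (input
functions rebuilt from blood samples, not taken from the truth).

## Known limitations

- The (V_ND, ∂max) ridge above: per-subject V_ND from a single scan is
  noisy, as the published per-subject spread also suggests.
- Emax fits from 11 subjects with integer-rounded exposure inputs leave
  the IC50 of a flat (low-R²) curve sensitive at the few-percent level.
- The single-step solution systematically underestimates occupancy for
  slowly entering drugs at low doses; the pipeline reports both
  solutions so the discrepancy is visible.
- Lassen occupancies outside [0, 100] % (possible under noise) are
  clamped when tabulated into occupancy records.
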