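# Methods

## Problem

After cataract surgery the implanted intraocular lens (IOL) determines the
eye's refraction. IOL power formulas predict, from preoperative biometry
(axial length AL, mean keratometry Km, anterior chamber depth ACD, …), the
postoperative spherical-equivalent refraction an eye will have for a given
implanted power. Each formula carries an empirical lens constant
(A-constant, personalized ACD, surgeon factor, or the Haigis a0) that
absorbs lens-, surgeon- and population-level effects; transplanting a
formula to a new population without re-deriving its constant is a known
source of systematic prediction error.

`iolbench` implements four published vergence formulas (SRK/T, Hoffer Q,
Holladay 1, Haigis — exact variants in `formula_provenance.md`), optimizes
their constants to zero the mean prediction error on a training split,
calibrates closed-source formulas by mean-error offset, and compares
formulas with the error metrics and statistical battery standard in the
IOL-accuracy literature.

## Prediction error and metrics

The prediction error of an eye is `e = predicted − measured` 1-month
spherical-equivalent refraction (this sign convention is pinned throughout;
a positive ME means the formula predicts more hyperopia than observed).
Reported metrics: ME = mean(e), MAE = mean|e|, MedAE = median|e|,
RMSAE = sqrt(mean e²), SD = sample standard deviation of e (n−1
denominator), and the percentage of eyes with |e| ≤ t for
t ∈ {0.25, 0.5, 0.75, 1.0} D (inclusive thresholds, the common reporting
convention). These satisfy MAE ≤ RMSAE and RMSAE² = ME² + SD²·(n−1)/n,
which the tests assert to 1e−12.

## Constant optimization

Predicted refraction is strictly increasing in each formula's scalar
constant (a deeper assumed lens position makes the same power "weaker",
shifting the prediction hyperopic) and strictly decreasing in IOL power;
both monotonicities are asserted empirically. The training-set mean error
ME(c) is therefore strictly monotone in the constant and "optimization to
zero mean error" is bracketed root-finding: Brent's method on ME(c) over
A ∈ [110, 125], pACD ∈ [2, 9] mm, SF ∈ [−2, 5] mm, a0 ∈ [−3, 3] mm, with a
7-point monotonicity scan and a sign-change check that raises with a
"widen the bracket" instruction when the zero lies outside. The returned
constants reproduce |training ME| < 1e−6 D (asserted on every run). During
bracket scanning the (0, AL) lens-position validity check is suspended —
bracket endpoints can be nonphysical — and re-applied to the final answer.
Only the scalar constant moves; the Haigis a1 = 0.4, a2 = 0.1 stay fixed
(single-constant mode; triple optimization is out of scope).

Closed-source formulas (e.g. online-calculator outputs supplied as
per-eye prediction files) cannot have their constants touched, so they are
calibrated by subtracting the training-set mean error from every
prediction. Because ME is locally linear in the constant, the offset and a
constant shift are interchangeable to first order; a test confirms the two
routes agree on held-out MAE to 0.02 D at n = 2000.

## Train/test discipline

Cohorts are split 70/30 by a uniform permutation under an explicit integer
seed (sizes `round(0.7·n)` and the remainder). Constants and offsets are
fit on the training split only; every optimized-context metric is computed
on the held-out split, and the pipeline asserts the two id sets are
disjoint and records the audit in the report manifest.

## Statistical battery

- Formula-vs-formula: Friedman test across formulas on the absolute errors
  of the same eyes, then all pairwise two-sided Wilcoxon signed-rank tests
  with Bonferroni correction (adjusted p = min(1, raw·m), m = number of
  pairs), significance at α = 0.05. Wilcoxon zero differences use the
  Pratt method (software defaults differ; pinned here). A matrix whose
  columns are all identical is reported exactly as statistic 0, p = 1
  (scipy's tie correction degenerates there).
- Before/after constants: two-sided paired t-test on absolute errors.
  Zero-variance difference vectors are degenerate for t; they are reported
  with a warning as p = 1 (no change) or p = 0 (uniform change).
- Cohort contrasts: per-variable two-sided Student t-tests (between
  cohorts and between sexes within a cohort). Laterality is a count
  variable, for which a t-test is ill-posed; it is compared as right-eye
  proportions with a two-proportion z-test, noted in the table.

## Synthetic cohorts

No per-eye clinical data ship with the package; the simulator generates
cohorts with the structure the pipeline assumes.

1. **Biometry**: joint normal over (age, AL, ACD, LT, CCT, WTW, K1, K2)
   with profile means/SDs, truncated by rejection to the plausibility
   bounds used by the eligibility filter. Correlations are stipulated,
   transparent defaults (AL–ACD +0.45, AL–K −0.35, AL–LT −0.20, K1–K2
   +0.90, others 0) chosen for qualitative realism; they are simulator
   inputs, not estimates of any real cohort.
2. **Refraction target**: per-eye draw from the profile's practice
   pattern — the `aravind_like` profile targets near-emmetropia
   (mean +0.10 D, SD 0.33), the `umich_like` profile a more myopic, more
   dispersed mix (mean −0.59 D, SD 0.93).
3. **Power selection**: the implanted power is the half-diopter grid value
   in [6, 30] D whose ground-truth-formula prediction is closest to the
   target (ties to the lower power), mimicking surgeon selection. The
   truth formula defaults to SRK/T at A = 119.082 — deliberately the same
   code path the pipeline tests (a closed loop), with the option to
   generate from Haigis for cross-formula checks.
4. **Measured refraction**: truth prediction plus N(0, 0.30² D²) noise.
   0.30 D reflects the typical SD of refraction prediction error for
   modern formulas on average eyes; with target-policy spread it yields a
   postoperative refraction SD near the narrow-target population's
   published 0.33 D.

Built-in profile means (age 60.52/70.73 y, AL 23.19/24.15 mm with SD
0.94/1.35, ACD 3.28/3.25, LT 4.24/4.53, CCT 526/553 µm, WTW 11.89/12.09,
K1 44.20/43.44, K2 44.86/44.32 D; sex and laterality mixes) encode the
published summary statistics of the two emulated populations. SDs the
summaries do not print use documented defaults (age 9.5 y, ACD 0.35, LT
0.40 mm, CCT 33 µm, WTW 0.45 mm, K 1.5 D).

**What passing tests show — and don't.** The simulator reproduces marginal
moments, the practice-pattern direction contrast, and the closed-loop
constant-recovery behaviour. It does not model the skewed long-eye tail,
cataract grading, biometer-specific measurement error, or real
within-cohort correlation structure, so quantitative agreement with any
real cohort's error tables is not expected — only the directional pattern
(which population is shorter/younger/steeper, spread ordering) and the
methodological phenomena (held-out MAE improves after constant
optimization; optimized training ME is zero).

## Numerical choices and degenerate inputs

- Root-finding: `scipy.optimize.brentq`, xtol 1e−12; required |ME| < 1e−6 D.
- K1/K2 are canonicalized (swapped if flat > steep) at record construction
  and in the simulator; astigmatism is therefore always ≥ 0, which folds
  the K1>K2 draws and slightly inflates mean simulated astigmatism.
- Eligibility reasons are evaluated in a fixed order (missing/out-of-bounds
  → acuity → lens model → second eye), first match recorded; duplicate
  patients keep the earlier file row (deterministic, auditable).
- "Within t D" thresholds are inclusive; boundary behaviour unit-tested.
- Cohort files round floats at 6 significant digits; the write→read
  round-trip is the identity to that precision.
- Report bundles are pure functions of (config, seed): JSON is written
  with sorted keys, CSV with fixed float formatting, no timestamps —
  identical runs are byte-identical.

## Problem sizes

The shipped study configuration simulates 985 + 1003 eyes (the sizes of
the two populations the profiles emulate) with a 70/30 split; recovery
experiments use n = 2000 (and n = 200 for the scaling check). These sizes
give sub-second end-to-end runs while leaving Monte-Carlo error well below
the effect sizes being tested.

## Known limitations

- Single-lens, spherical-equivalent world: toric IOLs and astigmatism
  prediction are out of scope; refractions are SE only.
- Barrett Universal II, Pearl-DGS, Nallasamy and similar closed-source or
  weights-unavailable formulas are supported only through external
  prediction files plus offset calibration, clearly labeled as such.
- Haigis runs in single-constant mode; a (a0, a1, a2) joint fit is future
  work, as are bootstrap confidence intervals on constants.
- The shipped Haigis default a0 = −0.739 (with a1 = 0.4, a2 = 0.1) implies
  a shallow effective lens position and a strongly myopic bias on typical
  eyes; it is a published population-optimized value retained as the
  starting point, and the pipeline re-optimizes a0 before any optimized
  context is reported.
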