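# Methods

This note documents the statistical model, the estimators and their
numerical choices, the synthetic cohort generator, and the limits of what
the test suite demonstrates.

## Measurement model and LOAM

A complete grid of volumes `Y_ij` (subject i = 1..n, observer j = 1..m,
mm³) is modelled as

    Y_ij = μ + a_i + b_j + e_ij,
    b_j ~ N(0, σ_O²),   e_ij ~ N(0, σ_R²),

where `b_j` is a systematic observer offset shared across subjects and
`e_ij` random, unrepeatable annotation error. Subject effects `a_i` are
treated as fixed: every agreement quantity is built from deviations from
subject means, in which they cancel, so no distributional assumption on the
case mix is needed. The between-subject mean square is still computed — the
ICC requires it.

The limits of agreement with the mean bound the deviation of one
measurement from the m-observer mean of the same subject. Under the model

    Var(Y_ij − Ȳ_i·) = (m−1)/m · (σ_O² + σ_R²),

so `LOAM = z·sqrt((m−1)/m·(σ_O² + σ_R²))` with `z` the exact standard-normal
0.975 quantile (1.959964…, not the rounded 1.96, so point estimates and CI
bounds transform identically). The `(m−1)/m` factor is exact for finite m;
a switch (`finite_observer_correction=False`) drops it for sensitivity
analysis against the infinite-observer convention, where it changes LOAM by
`sqrt(m/(m−1))` (+11.8% at m = 5).

Components are method-of-moments from the two-way crossed ANOVA without
interaction: `σ̂_R² = MS_R`, `σ̂_O² = (MS_O − MS_R)/n`. A negative observer
moment — common when the true observer variance is small relative to
`σ_R²/n` and m is small — is truncated to 0 and flagged; the raw value is
retained for diagnostics. The LOAM *point* estimate uses the truncated
components; its CI is built around the untruncated linear combination (see
below) and widened, if necessary, to envelop the point estimate so the
reported triple is always ordered.

## Confidence intervals

**LOAM.** `ψ = σ_O² + σ_R² = (1/n)·MS_O + ((n−1)/n)·MS_R` is a positive
linear combination of independent scaled-χ² mean squares, so the modified
large-sample (Graybill–Wang) interval applies:

    high = ψ̂ + sqrt(Σ_k (H_k c_k MS_k)²),   H_k = df_k/χ²(α/2; df_k) − 1,
    low  = ψ̂ − sqrt(Σ_k (G_k c_k MS_k)²),   G_k = 1 − df_k/χ²(1−α/2; df_k),

clamped below at 0 and mapped through `z·sqrt((m−1)/m·ψ)`. The interval is
asymmetric — strongly so for small m, where `df_O = m−1` makes the upper
χ² factor large. Simulated coverage at the n = 26, m = 5 design is ≈ 0.95
(the acceptance suite checks 0.93–0.97 over 1000 replicates).

**Component SDs.** No closed interval with good small-m behaviour exists
for the truncated `σ̂_O`, so both component SDs get a seeded parametric
bootstrap (default 10,000 resamples): mean squares are redrawn from their
fitted scaled-χ² laws (`E[MS_O] = n·σ̂_O² + σ̂_R²`, `E[MS_R] = σ̂_R²`),
components recomputed with the same truncation, and percentile intervals
taken on the SD scale. Lower bounds truncate at 0, which reproduces the
characteristic `σ̂_O = 2 (0–7)`-style rows of reliability tables. Fewer
than 100 resamples is refused; coverage for `σ_R` at 2000 resamples is
≈ 0.95 by simulation.

**ICC.** Two-way random, absolute agreement, single measure:

    ICC(A,1) = (MS_S − MS_R) / (MS_S + (m−1)MS_R + (m/n)(MS_O − MS_R)),

with the standard F-based interval using Satterthwaite degrees of freedom
for the denominator combination (McGraw–Wong). The implementation is
cross-checked in the tests against pingouin's `ICC(A,1)` row to machine
precision on the value and to its printed precision on the CI. A fully
degenerate grid (zero total variance) raises `DegenerateDataError`; the
`LoamAgreement` estimator converts that to an NaN ICC so pipelines on
pathological inputs still complete.

## Stratification and cyst exclusion

Quartile strata are contiguous rank blocks of the per-subject *average
observed* volume (stable sort, remainder to the lowest strata), not
interpolated quantile thresholds: this guarantees the exact 25/25/25/25
split for n = 100 and makes stratum membership reproducible under ties.
The cyst-exclusion sensitivity analysis removes cyst-flagged subjects
*within* their full-cohort stratum rather than re-stratifying, so excluded
rows keep their original labels and cyst-free strata are bit-identical
between the two analyses. A stratum reduced below 2 subjects is skipped
with a warning.

## Sliding window and the per-volume calculator

Subjects sorted by average observed volume are covered by every contiguous
block of w subjects (step 1, default w = 26 — the reliability-study sample
size, so each window is an adequately powered agreement study). Each window
gets the full LOAM stack; the abscissa is the arithmetic mean of member
subject means. Consecutive windows differ by exactly one subject dropped
and one added.

`loam_lookup` interpolates LOAM% and its CI bounds piecewise-linearly in
**log volume** (volumes span two orders of magnitude; linear-in-log is the
least surprising monotone choice); out-of-range volumes clamp to the
nearest end with an `extrapolated` flag.

`threshold_crossing` locates where the curve settles below a reference
line (default: the CI upper bound against 20%). The default `persistent`
rule demands the tracked value stay below the line for all larger-volume
windows, because a noisy curve can dip below and bounce back; `first`
takes the first touch. On noisy curves these two readings bracket the
underlying crossing — first-touch is biased low, persistence high (about
−19%/+22% at n = 1000, w = 26 in generator experiments) — so a third rule,
`bracket`, returns their geometric mean as the low-bias point estimate and
is what the reproduction script reports. The crossing volume itself is
read off by log-volume interpolation between the qualifying window and its
predecessor.

## Covariate regression

The response is the per-subject relative volume SD, `SD_V% = 100·SD/mean`
(sample SD over the m observer values). Each covariate is screened in a
single-covariate OLS with intercept (t-based CIs and p-values,
complete-case per covariate); covariates with screening p < 0.05 enter one
joint OLS whose coefficients are reported as adjusted. Coding: laterality
L=0/R=1, cyst no=0/yes=1, field strength numeric in tesla, acquisition
date as decimal years. Constant covariates are flagged inestimable rather
than dropped silently; designs with condition number above 1e8 are flagged
collinear (statsmodels' pseudo-inverse fit is then reported, with a
warning). No multiplicity correction is applied — the workup is the
classical univariable screen → multivariable confounding check, not a
discovery procedure.

## Sample size (assurance)

The reliability design is sized so that the one-sided (1−α) lower
confidence limit of the one-way random-effects ICC exceeds the minimum
acceptable ρ₀ with probability ≥ the target when the true ICC is ρ. With
θ = ρ/(1−ρ), `F/(1+mθ) ~ F(n−1, n(m−1))` and the limit exceeds ρ₀ iff
`F > (1+mθ₀)·F_{1−α}`, giving the exact closed form

    power(n) = P( F(n−1, n(m−1)) > (1+mθ₀)/(1+mθ) · F_{1−α; n−1, n(m−1)} ).

The one-way model with a one-sided limit is the combination that makes the
reference design (ρ = 0.9, ρ₀ = 0.8, power 0.8, α = 0.05, m = 5) resolve
to n = 26 — power 0.796 at n = 25 and 0.809 at n = 26 — and is calibrated
to that printed figure; a two-way model or two-sided limit yields other
values. The search is exponential-plus-bisection (power is monotone in n,
verified by scan in the tests), and the analytic power is cross-checked by
10,000-replicate simulation of one-way ICC studies.

## Synthetic cohort generator

The generator emulates a single-center volumetric annotation study:

* **True volumes** `V_i`: log-normal, median 903 mm³, ln-scale 2.06
  (chosen so the quartile ratio matches an observed IQR of 193–3101 mm³),
  redrawn outside [30, 25000] mm³. The truncation reflects purposive
  clinical sampling — cohort summaries show no multi-hundred-cm³ tumors,
  while an untruncated ln-scale-2.06 log-normal produces them; the cut is
  near-symmetric in quantile space, so the median stays ≈ 903 mm³.
* **Measurements** `Y_ij = V_i + (b_j + e_ij)·V_i^γ` with
  `b_j ~ N(0, τ_O²)`, `e_ij ~ N(0, τ_R²)`. Additive error scaled by `V^γ`
  (rather than multiplicative log-normal error) reproduces the central
  phenomenon — relative limits fall with volume — with one interpretable
  parameter. γ = 2/3 encodes surface-area scaling: segmentation
  disagreement accrues on the tumor boundary. Defaults τ_O = 0.225,
  τ_R = 0.674 (residual-dominated, as observed in practice) put the
  closed-form LOAM% at 26.8 for a 100 mm³ tumor, 12.5 at 1000 mm³, and the
  20% crossing at 242 mm³. Non-positive draws (possible only for tiny
  tumors) are redrawn cell-wise.
* **Cysts**: a fraction (default 0.12) of the top-volume half carries a
  peritumoral-cyst flag that multiplies its residual scale (default 2×,
  a free parameter — no quantitative cyst-effect model is established), so
  inclusive vs cyst-excluded analyses differ in the large strata only.
* **Covariates**: demographics and MRI acquisition parameters with a
  volume-linked confounding map — 3.0 T scans only among the largest
  quartile, thinner slices for larger tumors, echo time tracking field
  strength. None of them enters the error model, so any association with
  `SD_V%` is purely volume-mediated; the regression stage should (and in
  tests does, as a majority pattern over 20 seeds) find them significant
  univariably and not after volume adjustment.

The closed forms `analytic_loam_percent` and `analytic_threshold_volume`
are exact under the cyst-free model and serve as oracles: curve-fit checks
run with `cyst_fraction = 0` because cyst inflation is deliberately outside
the closed form (it is tested separately as a one-sided residual-variance
increase in the top stratum).

What the generator does **not** emulate: image-level segmentation
artifacts, observer-by-subject interactions (e.g. raters who disagree only
on cystic tumors), drift of observer bias over time, repeated measurements
per observer, or missing cells. Passing tests therefore demonstrate the
estimators are correct under the stated model and calibration, not that
real cohorts meet those assumptions.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to keep Monte-Carlo error well
inside the asserted bands: 1000 replicates for CI coverage (binomial SE
≈ 0.7%), 400–1000 replicates for unbiasedness (asserted at 3 MC SEs),
n = 1000 cohorts for curve-vs-oracle comparisons (per-window sampling
error ≈ 7%, asserted relative RMSE < 10%), and 3 seeds averaged
geometrically for the crossing estimate (single-seed spread ≈ ±20% around
the analytic 242 mm³). Bootstrap defaults are 10,000 resamples for
reported tables and 2,000 inside the sliding window, where the bootstrap
is ancillary (curve CIs are analytic MLS).

Determinism: every stochastic component takes a seed or Generator;
sliding-window bootstraps derive per-window seeds from a single
`SeedSequence` spawn, so curves are reproducible regardless of window
count. Ties in volume ranking are broken by stable sort on input order.
Degenerate inputs: constant grids give zero mean squares, zero LOAM and an
NaN ICC (flagged, not raised, at the estimator level); zero-variance CIs
collapse to (0, 0).

## Known limitations

* The LOAM CI treats ψ's mean squares as independent χ²; with truncated
  observer components the interval is conservative near σ_O² = 0.
* The bootstrap component intervals are percentile-type; they inherit the
  usual slight undercoverage for very small df_O.
* The crossing estimator interpolates a noisy step curve; its `bracket`
  reading is low-bias but not variance-optimal, and single-seed estimates
  at n = 100 remain volatile (the CI-upper-bound crossing especially —
  it reflects evidence strength, not just the underlying curve).
* The regression stage fits linear volume effects while the generated
  relationship is a power law; with heavy right tails the linear volume
  adjustment can leave residual structure for volume-linked covariates in
  a minority of seeds. This mirrors the practical workup it reproduces.
* One-way assurance sizing is a deliberate calibration choice; other model
  forms are out of scope.
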