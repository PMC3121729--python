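# Methods

## The outcome: medication possession ratio

For each patient and drug class (insulin, HS501; oral hypoglycemics,
HS502) refill windows of 90 days are anchored at the first fill — 90 days
because that is the typical mail-order supply cycle in the population this
models. Windows continue until the class becomes inactive, defined as the
latest `fill date + days supplied` over same-day-aggregated fills; the
final window is truncated there, contributing only its actual calendar
days to the denominator. Aggregating same-day fills before computing the
inactivity date makes the measure invariant to splitting one dispensing
event into several same-day records, which raw claims data frequently do.

Supplied days are credited entirely to the window containing the fill
date; there is no carry-over or stockpiling model. Classes are pooled at
the patient level (eligible and supplied days summed across classes;
`per_class=True` exposes the alternative for sensitivity use), and

```
MPR = min(1, supplied days / eligible days)
```

with the cap applied to the final pooled ratio, not per window, so
overlapping same-class fills within a window simply sum and oversupply is
absorbed by the cap. Patients with zero eligible days have undefined MPR
and are excluded from model input with a logged warning. The per-window
ratios are reported uncapped for diagnostics only.

Consequences of the inactivity rule worth knowing: a single fill of 120
days yields *two* windows (90 + 30 eligible days) and MPR 1, not a capped
90-day window — a capped ratio requires overlapping fills inside a
window. Likewise a lone 45-day fill yields 45 eligible days (MPR 1), so
the refill-record generator pins the denominator explicitly (below).

## Quantile regression and the solver

The conditional quantile model is `Q_y(τ|x) = x'β_τ`, estimated by
minimizing the check loss `Σ_i ρ_τ(y_i − x_i'β)`,
`ρ_τ(r) = r(τ − 1[r<0])`; τ = 0.5 is median regression. The objective is
convex piecewise linear — an LP — and an optimal solution interpolates p
observations when the design has full column rank.

The solver runs three stages:

1. **Finite-smoothing Newton continuation.** The kink of ρ_τ is replaced
   by a quadratic of half-width γ (`r²/4γ + (τ−½)r + γ/4` on |r| ≤ γ),
   Newton directions are taken on the smoothed objective, and γ shrinks
   geometrically (×0.1 from `γ₀ = median|y − ȳ|` down to 1e-8). Step
   lengths come from an *exact line search on the true check loss*: along
   any direction the objective is piecewise linear in the step with kinks
   at `t_i = r_i/a_i` whose right derivative increases by `w_i|a_i|`, so
   the line minimizer is a weighted-median scan — each iteration lands
   exactly on a residual kink and backtracking is never needed. When the
   smoothing band holds fewer than p points the Hessian is singular and
   the iteration falls back to the subgradient direction, again stepped by
   exact line search. Per-stage iterations are capped at 15; the finisher
   below does the endgame exactly, so the continuation only needs to track
   the central path.
2. **Vertex polish** (p ≤ 8): solve the interpolation systems through
   subsets of the p+k smallest-|residual| rows (batched), keep any strict
   improvement, iterate. At larger p subset enumeration is combinatorial
   and is skipped in favor of stage 3.
3. **Certified edge descent.** From the current point, the active set is
   the zero-residual rows. At a vertex the edge directions are the columns
   of the inverse of the active-row matrix (relax one interpolation
   constraint at a time); below a vertex they are a null-space basis of
   the active rows. One-sided directional derivatives are computed
   analytically for all candidate directions at once, the steepest
   descending edge is walked by exact line search, and the loop stops when
   the exact subgradient certificate holds: dual weights
   `ξ_i ∈ [w_i(τ−1), w_i τ]` on the active rows with
   `Σ_act x_i ξ_i = −Σ_inact x_i w_i ψ_i` exist (a least-squares + box
   check when the active set has ≤ p rows, a small feasibility LP in the
   degenerate case). A fit is flagged `converged` only under this
   certificate; non-convergence is reported, never silent.

Duplicated (x, y) rows — ubiquitous in bootstrap resamples — are collapsed
into integer weights before solving. This keeps the solution polytope
non-degenerate and every stage above is weighted accordingly.

Solutions can be set-valued (flat optimal edges); the contract is the
optimal *objective*, and all cross-implementation tests compare
objectives, not coefficients. τ is clipped to `[0.5/n, 1 − 0.5/n]` with a
warning because extreme-order-statistic fits are fragile. Against the
brute-force `fit_exact` enumeration oracle the solver agrees to machine
precision on hundreds of random small instances, and on larger instances
its objective matches or beats an independent implementation
(statsmodels) to ~1e-5 relative.

**Inference.** Rank-inversion confidence intervals are out of scope;
single-fit inference is the xy-pair bootstrap: resample whole observations
with replacement (implemented as multinomial weights), refit, and take
exact empirical percentiles per coefficient — the smallest value whose
ECDF reaches the probability, no interpolation. The two-sided p-value is
the smallest level whose percentile interval excludes zero. B = 2
degenerates to the min/max of the two replicates, by construction.

## Mean-model comparators

`OLS` solves the normal equations and reports classical SEs with
Breusch–Pagan heteroscedasticity and D'Agostino normality diagnostics
always attached — for bounded skewed outcomes these assumptions typically
fail, and the comparison is the point, so the diagnostics are not
optional. `RandomInterceptLM` fits
`y_ij = x_ij'β + b_i + e_ij`, `b_i ~ N(0, σ²_subject)`,
`e_ij ~ N(0, σ²_resid)` by maximum likelihood profiled over the variance
ratio λ = σ²_subject/σ²_resid (per-group closed-form inverses; bounded
scalar search over λ with λ = 0 checked explicitly so boundary estimates
are exact). REML is available by flag; ML is the default. When every
subject contributes one observation the variance split is unidentifiable:
the fit warns, falls back to OLS fixed effects, and reports σ²_subject as
not estimable — an explicit contract rather than an ill-posed fit, since
cross-sectional comparisons only need the fixed effects anyway.

## Analysis pipeline

Race/ethnicity is treatment-coded against NHW with missing race folded
into "Other (including unknown/missing)"; marital status references
married, employment references unemployed; age is centered (default: the
sample mean) with an optional quadratic term; the eleven comorbidity flags
and the poor-glycemic-control flag enter as 0/1. Column order is
deterministic. Coefficients are *reported* ×100 (percentage points of
MPR) in every output table — the scale is stamped in the CSV header —
while computation stays on the proportion scale.

Quantile levels can be given directly or as clinical MPR cutoffs mapped
through the empirical CDF, right-continuous with ties counted as ≤ (so a
cutoff equal to a data value includes it); the inverse map is the τ-th
order statistic. Mapped levels are clipped away from {0, 1} with a
warning.

Leverage points (quantile regression is robust to outlying responses, not
to outlying covariates) are flagged by coordinatewise robust
standardization: each non-constant column centered at its median and
scaled by its normal-consistent MAD, squared distances compared with the
χ²(df = #usable columns) 0.975 quantile. Zero-MAD columns — rare dummies,
typically — are excluded with a warning, so in heavily categorical designs
the distance effectively screens the continuous coordinates. This simpler
estimator was chosen over a minimum-covariance-determinant fit because it
is deterministic, cheap and testable; flags are reported, observations are
never removed. The univariate screen (one median-regression and one OLS
fit per covariate) is descriptive only and never gates the adjusted model;
constant columns are skipped with a warning.

## Resampling study

The method comparison draws `n_per_replicate` *patients* (not rows) with
replacement per replicate, so repeated measures travel with their patient
and the mixed model's clustering survives; resampled duplicates are
relabeled as distinct subjects. Each replicate refits every requested
method at frozen quantile levels (mapped once on the source cohort), and
the aggregate reports mean estimate, SD-as-SE, exact 2.5/97.5 percentiles
and the failure count per cell. Replicate randomness derives from
(master seed, replicate index), so results are independent of execution
order. Failed replicate fits are recorded and excluded; more than 10%
failures aborts with diagnostics. The full-scale design (10,000
replications of 5,000 patients, `--full-scale`) is preserved behind a
desk default of 200 × 2,000, which keeps the study inside minutes on one
CPU while leaving Monte-Carlo error on aggregate means well below the
effects of interest.

## Synthetic cohort generator

Covariates are sampled independently at configured prevalences (defaults:
97.3% male, hypertension 25.7%, CHD 13.9%, substance use 14.4%, and so on;
age ~ N(66, 11.6²); race 51.5/29.7/18.8% NHW/NHB/Other among observed with
8.6% missing completely at random, folded into Other at encoding).
Categorical probability vectors are normalized at sampling time (the
configured employment shares sum to 99.8%). Outcomes come from the
inverse-quantile-function construction `Y = clamp(x'β(U) + b_i, 0, 1)`:
because `Q_Y(τ|x) = x'β(τ)` exactly wherever the clamp is inactive, any
planted curve is the literal estimand at every τ — no additive-error
approximation stands between the generator and the estimator. Curves are
supplied as callables or monotone-interpolated knot lists; the generator
validates that `x'β(τ)` is non-decreasing in τ over the realized covariate
profiles on a τ grid and rejects violating configurations, naming the
offending profile and τ pair. The repeated-measures mode adds the
patient-level Gaussian shift `b_i` on the latent scale before clamping,
giving the mixed model a known variance truth.

The `table1_like` preset produces a left-skewed bounded MPR (reference
profile median ≈ 0.97, IQR ≈ 0.12 via the intercept curve
`1 − 0.34(1−τ)^3.5`) and a race disparity shrinking from the lower to the
upper tail; its age curves are constant in τ because any τ-slope
multiplied by an extreme centered age would violate latent monotonicity.
It is a qualitative emulation for testing, not a reproduction of any
cohort: real adherence data have correlated comorbidities, informative
missingness, duration-of-therapy effects and measurement artifacts that
the generator deliberately omits, so passing recovery tests demonstrates
estimator correctness, not real-world validity.

`generate_refill_records` closes the loop with the MPR engine: for a
target ratio m and k windows it emits a history whose computed MPR is
`round(m·k·90)/(k·90)` exactly — full adherence as k fills of 90 days;
otherwise a bulk fill at the first window start plus a fill ending exactly
at day k·90 pin the denominator to k·90 eligible days. Because at least
one anchoring fill of ≥1 day is needed at each end, the smallest
representable supplied total is 2 days; targets below 2/(k·90) round up to
that floor.

## Numerical choices and defaults

- Smoothing schedule γ₀ = median|y − ȳ| (falling back to sd(y) if zero),
  shrink ×0.1, floor 1e-8; warm starts (bootstrap replicates) begin at
  γ₀ = 1e-4 × scale with the full-data solution as the initial point.
- Residuals count as zero within 1e-9 × max(1, |y|_∞); dual-box
  feasibility tolerance 1e-7; objective improvements below 1e-12 relative
  are treated as ties.
- Degenerate vertices (more than p active rows) are certified by a
  feasibility LP and pivoted by per-row null-space relaxation.
- LMM λ-search: bounded scalar minimization on log λ over [1e-10, 1e6]
  with xatol 1e-10; agreement with an independent implementation is to
  ~1e-5 on variance components, so invariance tests compare at optimizer
  precision, not machine precision.
- Bootstrap intervals use the order-statistic percentile definition
  (smallest value with ECDF ≥ prob) everywhere, including the resampling
  study's 2.5/97.5 summaries.
- Problem sizes in the test suite — 200 solver-oracle instances, planted
  recovery at n = 5,000, coverage over 500 simulations of n = 500 with
  B = 200, variance recovery at 2,000 subjects × 4 periods, resampling
  calibration at 200 replications of n = 2,000 — were chosen so each check
  has adequate statistical power while the whole suite stays within a few
  minutes on one CPU.

## Known limitations

- No carry-over/stockpiling in the MPR engine; no CMA/CMOS/MRA variants.
- No censored, longitudinal or penalized quantile regression; quantile
  crossing is reported, not rearranged.
- Mixed models are Gaussian random-intercept only (no random slopes or
  richer covariance structures).
- Bootstrap intervals are percentile-only (no BCa); p-values are raw, with
  no multiplicity adjustment across quantiles or terms.
- The leverage screen is coordinatewise, so it cannot see correlation-
  driven multivariate outliers; a heavier estimator can be plugged in
  through the same interface.
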