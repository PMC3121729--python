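# adherence-qreg

Quantile-regression analysis of medication adherence for pharmacoepidemiology:
who falls behind on refills, by how much, and where in the adherence
distribution the gaps live.

Medication adherence measured from pharmacy refill records — the medication
possession ratio (MPR), days of medication supplied divided by eligible days,
capped at 100% — is bounded, quasi-continuous and strongly left-skewed: most
patients sit near full adherence while a clinically critical minority trail
far behind. Mean-based regression (OLS, random-intercept mixed models)
summarizes a covariate's effect by a single shift of the conditional mean and
can miss disparities that are concentrated in the poorly adherent tail.
Conditional-quantile regression models

```
Q_y(τ | x) = x'β_τ,        β̂_τ = argmin_β Σ_i ρ_τ(y_i − x_i'β),
ρ_τ(r) = r·(τ − 1[r < 0])
```

so β_τ can differ across quantile levels τ, exposing effects on the tails
that the mean averages away. This package provides, as one tested pipeline:

- **`adherence_qreg.mpr`** — MPR construction from refill records: 90-day
  windows anchored at the first fill per drug class (insulin HS501, oral
  agents HS502), eligible days truncated at the inactivity date, classes
  pooled per patient, ratio capped at 1.
- **`adherence_qreg.quantreg`** — a `QuantReg` model whose `fit(tau)`
  minimizes the check loss by a finite-smoothing Newton continuation with a
  certified piecewise-linear finisher; `fit_exact` is a brute-force
  enumeration oracle for small instances; xy-pair bootstrap percentile CIs.
- **`adherence_qreg.mean_models`** — the mean-model comparators: `OLS`
  (normal equations, classical SEs, residual diagnostics always attached)
  and `RandomInterceptLM` (profiled-ML random-intercept linear mixed model).
- **`adherence_qreg.pipeline`** — `DisparityAnalysis`: covariate encoding
  with race/ethnicity treatment-coded against non-Hispanic White (NHW),
  empirical-CDF mapping between clinical MPR cutoffs and quantile levels,
  multi-method comparison tables, robust leverage-point flags, and
  predicted-MPR-by-age curve tables.
- **`adherence_qreg.resampling`** — the method-comparison study: resample
  patients with replacement, refit every method per replicate, aggregate
  means, SD-as-SE and exact 2.5/97.5 percentiles.
- **`adherence_qreg.cohort`** — a synthetic-cohort generator whose
  conditional quantile structure is user-controlled: outcomes are drawn by
  inverse-transform sampling `Y = clamp(x'β(U), 0, 1)` with `U ~ U(0,1)`, so
  any planted coefficient curve `β_j(τ)` is the *exact* estimand of quantile
  regression and every downstream stage can be validated against a known
  truth without access to any cohort data.

## Worked example

Simulate a cohort with a built-in disparity preset (race effect on MPR
shrinking from the lower to the upper tail), then compare quantile fits at
clinically meaningful MPR cutoffs against OLS:

```python
import warnings
from adherence_qreg import (
    DisparityAnalysis, ModelSpec, generate_covariates, generate_mpr,
    table1_like_config, table1_like_qcf,
)

cfg = table1_like_config(n_patients=5_000, seed=7)
cohort = generate_covariates(cfg)
outcomes = generate_mpr(cohort, table1_like_qcf(), seed=8)
df = outcomes.merge(cohort, on="patient_id")
print(f"median MPR: {df['mpr'].median():.3f}   IQR: "
      f"{df['mpr'].quantile(0.75) - df['mpr'].quantile(0.25):.3f}")

spec = ModelSpec(cutoffs=(0.70, 0.80, 0.90, 0.95))
analysis = DisparityAnalysis(df, spec)
comp = analysis.fit_all(methods=("qreg", "ols"), adjusted=False,
                        n_boot=200, seed=9)
print("cutoff -> tau:", dict(zip(spec.cutoffs, comp.meta["taus"])))
nhb = comp.table[comp.table["term"] == "race_NHB"]
print(nhb[["method", "tau", "estimate", "ci_low", "ci_high", "p"]]
      .round(3).to_string(index=False))
```

which prints

```
median MPR: 0.953   IQR: 0.127
cutoff -> tau: {0.7: 0.0594, 0.8: 0.1596, 0.9: 0.33, 0.95: 0.4864}
method   tau  estimate  ci_low  ci_high   p
  qreg 0.059    -5.690  -7.016   -4.128 0.0
  qreg 0.160    -5.011  -6.482   -2.956 0.0
  qreg 0.330    -3.742  -5.112   -2.414 0.0
  qreg 0.486    -3.040  -3.798   -2.195 0.0
   ols   NaN    -2.789  -3.460   -2.118 0.0
```

Reading the table (estimates are percentage points of MPR, ×100 from the
proportion scale): an MPR cutoff of 0.70 sits at the 5.9th percentile of
this cohort's adherence distribution, and at that level non-Hispanic Black
patients have a 5.7-point lower MPR than NHW patients with a 95% bootstrap
percentile interval of (−7.0, −4.1). The disparity shrinks monotonically
toward the median (−3.0 points at τ ≈ 0.49), exactly the planted pattern —
while OLS reports only a single averaged −2.8-point effect and says nothing
about where in the distribution the gap is concentrated.

The same analysis is scriptable from the shell:

```bash
adherence-qreg simulate --n 5000 --seed 7 --out cohort.csv
adherence-qreg compare --cohort cohort.csv --scenario cutoffs=0.7,0.8,0.9,0.95 \
    --adjusted --boot 200 --seed 9 --out results/
adherence-qreg bootstrap --cohort cohort.csv --scenario taus=0.1,0.3,0.5 \
    --reps 200 --n 2000 --seed 7 --out study/
```

plus `compute-mpr` for turning a refill file
(`patient_id,drug_class,fill_date,days_supplied`) into an MPR table.

## Limitations

The solver reports set-valued optima through the objective (quantile
solutions need not be unique); quantile crossing is reported, not repaired;
and the mixed model covers the random-intercept structure only. See
`docs/methods.md` for the model details, generator assumptions, and the
numerical choices behind the solver.
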