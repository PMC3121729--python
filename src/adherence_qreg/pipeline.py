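"""End-to-end disparity analysis: encoding, scenarios, fits, diagnostics.

Race/ethnicity is the primary covariate (treatment-coded against
non-Hispanic White, with missing race folded into "Other"); adjustment
covariates are sex, centered age (optionally with its square), marital
status, employment, and the binary comorbidity flags.  Quantile levels
can be specified directly or through clinically meaningful MPR cutoffs
mapped via the empirical CDF (right-continuous, ties counted as <=).
Fitted coefficients are reported on the percent (MPR x 100) scale in all
output tables; internal computation stays on the proportion scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BINARY_COVARIATES
from .mean_models import OLS, RandomInterceptLM
from .quantreg import QuantReg

PERCENT_SCALE_NOTE = "coefficients on the percent (MPR x 100) scale"


@dataclass
class ModelSpec:
    """Covariate and quantile-scenario specification.

    ``cutoffs`` (MPR values in (0,1)) and ``taus`` are mutually exclusive
    ways to choose the quantile levels; cutoffs are translated through
    the outcome's empirical CDF at fit time.  ``age_center`` defaults to
    the sample mean age.
    """

    outcome: str = "mpr"
    race_col: str = "race"
    race_ref: str = "NHW"
    race_levels: tuple = ("NHB", "Other")
    marital_ref: str = "married"
    employment_ref: str = "unemployed"
    binary_covariates: tuple | None = None  # None -> all known flags present
    age_center: float | None = None
    include_age_squared: bool = True
    cutoffs: tuple | None = None
    taus: tuple | None = None

    def __post_init__(self):
        if self.cutoffs is not None and self.taus is not None:
            raise ValueError("specify cutoffs or taus, not both")
        for v in itertools.chain(self.cutoffs or (), self.taus or ()):
            if not 0.0 < v < 1.0:
                raise ValueError(f"cutoffs and taus must lie in (0, 1), got {v}")

    def quantile_levels(self, outcome_values) -> list[float]:
        if self.taus is not None:
            return [float(t) for t in self.taus]
        if self.cutoffs is not None:
            return list(cutoff_to_tau(outcome_values, self.cutoffs))
        return [0.5]


def encode_design(cohort: pd.DataFrame, spec: ModelSpec, adjusted: bool = True):
    """Treatment-coded design matrix with deterministic column order.

    Returns ``(X DataFrame with leading const column, meta dict)``; meta
    records the age centering constant and the category levels seen, so
    prediction-time encoding can reject unseen categories.
    """
    n = len(cohort)
    x = pd.DataFrame(index=cohort.index)
    x["const"] = 1.0
    race = cohort[spec.race_col].fillna("Other")
    seen = set(race.unique())
    allowed = {spec.race_ref, *spec.race_levels}
    unseen = seen - allowed
    if unseen:
        raise ValueError(f"unseen race categories: {sorted(unseen)}")
    for lev in spec.race_levels:
        x[f"race_{lev}"] = (race == lev).astype(float)
    meta = {"n": n, "race_levels": sorted(allowed), "scale": PERCENT_SCALE_NOTE}
    if adjusted:
        if "male" in cohort:
            x["male"] = cohort["male"].astype(float)
        center = (
            float(cohort["age"].mean()) if spec.age_center is None else float(spec.age_center)
        )
        meta["age_center"] = center
        x["age_c"] = cohort["age"].astype(float) - center
        if spec.include_age_squared:
            x["age_c2"] = x["age_c"] ** 2
        if "marital" in cohort:
            levels = [l for l in cohort["marital"].unique() if l != spec.marital_ref]
            if spec.marital_ref not in set(cohort["marital"]):
                raise ValueError(f"marital reference {spec.marital_ref!r} not in data")
            for lev in sorted(levels):
                x[f"marital_{lev}"] = (cohort["marital"] == lev).astype(float)
            meta["marital_levels"] = sorted(set(cohort["marital"]))
        if "employment" in cohort:
            if spec.employment_ref not in set(cohort["employment"]):
                raise ValueError(
                    f"employment reference {spec.employment_ref!r} not in data"
                )
            levels = [l for l in cohort["employment"].unique() if l != spec.employment_ref]
            for lev in sorted(levels):
                x[f"employment_{lev}"] = (cohort["employment"] == lev).astype(float)
            meta["employment_levels"] = sorted(set(cohort["employment"]))
        flags = (
            spec.binary_covariates
            if spec.binary_covariates is not None
            else tuple(c for c in BINARY_COVARIATES if c != "male" and c in cohort)
        )
        for name in flags:
            x[name] = cohort[name].astype(float)
    return x, meta


def cutoff_to_tau(values, cutoffs):
    """Quantile level of each MPR cutoff under the empirical CDF.

    Right-continuous with ties counted as <= (``F(y) = P(Y <= y)``);
    results are clipped away from {0, 1} to [0.5/n, 1 - 0.5/n] with a
    warning, since quantile fits at the extreme order statistics are
    fragile.
    """
    y = np.sort(np.asarray(values, dtype=float))
    n = y.size
    if n == 0:
        raise ValueError("empty sample")
    cutoffs = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if ((cutoffs <= 0) | (cutoffs >= 1)).any():
        raise ValueError("cutoffs must lie in (0, 1)")
    taus = np.searchsorted(y, cutoffs, side="right") / n
    lo, hi = 0.5 / n, 1.0 - 0.5 / n
    clipped = np.clip(taus, lo, hi)
    if (clipped != taus).any():
        warnings.warn(
            f"cutoff-to-tau mapping hit the sample boundary; taus clipped to "
            f"[{lo:.4g}, {hi:.4g}]"
        )
    return clipped


def tau_to_cutoff(values, taus):
    """Inverse mapping: the tau-th order statistic of the sample."""
    y = np.sort(np.asarray(values, dtype=float))
    n = y.size
    if n == 0:
        raise ValueError("empty sample")
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    if ((taus <= 0) | (taus >= 1)).any():
        raise ValueError("taus must lie in (0, 1)")
    k = np.maximum(np.ceil(n * taus).astype(int), 1) - 1
    return y[np.minimum(k, n - 1)]


@dataclass
class ComparisonTable:
    """Tidy coefficient table across methods (the shape of an adjusted
    multi-method comparison), plus the fitted results for reuse."""

    table: pd.DataFrame
    fits: dict
    meta: dict = field(default_factory=dict)

    def to_csv(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {PERCENT_SCALE_NOTE}\n")
            self.table.to_csv(fh, index=False)

    def summary(self):
        head = [
            f"Method comparison on n = {self.meta.get('n')} rows; "
            f"{PERCENT_SCALE_NOTE}",
            f"  quantile levels: {self.meta.get('taus')}"
            + (
                f" (from cutoffs {self.meta.get('cutoffs')})"
                if self.meta.get("cutoffs")
                else ""
            ),
        ]
        return "\n".join(head) + "\n" + self.table.to_string(index=False)


class DisparityAnalysis:
    """Model-comparison analysis of one cohort table.

    Construct from a long-format cohort table carrying the outcome column
    (one row per patient, or per patient x period for the mixed model),
    then ``fit_all`` fits quantile regression at each scenario level plus
    the OLS and random-intercept comparators on an identical design.
    """

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec | None = None):
        self.cohort = cohort.reset_index(drop=True)
        self.spec = spec or ModelSpec()
        if self.spec.outcome not in self.cohort:
            raise ValueError(f"outcome column {self.spec.outcome!r} missing")

    @classmethod
    def from_dataframe(cls, cohort, spec=None):
        return cls(cohort, spec)

    def design(self, adjusted=True):
        x, meta = encode_design(self.cohort, self.spec, adjusted=adjusted)
        y = self.cohort[self.spec.outcome].to_numpy(dtype=float)
        return x, y, meta

    def fit_all(
        self,
        methods=("qreg", "ols", "lmm"),
        adjusted: bool = True,
        n_boot: int = 0,
        seed: int = 0,
    ) -> ComparisonTable:
        """One tidy table covering quantile fits at every scenario level
        plus the mean models; non-converged fits are flagged, not dropped.

        ``n_boot > 0`` attaches xy-pair bootstrap percentile CIs and
        p-values to the quantile rows; mean models carry classical
        t-based inference.
        """
        x, y, meta = self.design(adjusted=adjusted)
        taus = self.spec.quantile_levels(y)
        meta.update(
            {
                "taus": [round(float(t), 6) for t in taus],
                "cutoffs": list(self.spec.cutoffs) if self.spec.cutoffs else None,
                "adjusted": adjusted,
            }
        )
        rows, fits = [], {}
        if "qreg" in methods:
            model = QuantReg(y, x)
            for j, tau in enumerate(taus):
                res = model.fit(tau)
                fits[("qreg", res.tau)] = res
                if n_boot > 0:
                    ci = res.bootstrap_ci(n_boot=n_boot, seed=seed + j)
                    for _, r in ci.iterrows():
                        rows.append(
                            (r["term"], "qreg", res.tau, 100 * r["estimate"],
                             100 * r["ci_low"], 100 * r["ci_high"], r["p"],
                             res.converged)
                        )
                else:
                    for term, est in zip(x.columns, res.params):
                        rows.append(
                            (term, "qreg", res.tau, 100 * est, np.nan, np.nan,
                             np.nan, res.converged)
                        )
        for method in ("ols", "lmm"):
            if method not in methods:
                continue
            if method == "ols":
                res = OLS(y, x).fit()
            else:
                res = RandomInterceptLM(y, x, self.cohort["patient_id"].to_numpy()).fit()
            fits[(method, None)] = res
            ci = res.conf_int()
            for term, est, lo, hi, p in zip(
                x.columns, res.params, ci[:, 0], ci[:, 1], res.pvalues()
            ):
                rows.append(
                    (term, method, np.nan, 100 * est, 100 * lo, 100 * hi, p,
                     res.converged)
                )
        table = pd.DataFrame(
            rows,
            columns=["term", "method", "tau", "estimate", "ci_low", "ci_high", "p",
                     "converged"],
        )
        return ComparisonTable(table=table, fits=fits, meta=meta)

    def univariate_screen(self) -> pd.DataFrame:
        """Single-covariate association screen (descriptive only).

        One median-regression and one OLS fit per encoded covariate
        column; p-values are classical t-tests from the OLS fit (the
        quantile rows report the estimate only).  Screening never gates
        the adjusted model.
        """
        x, y, _ = self.design(adjusted=True)
        rows = []
        skipped = [c for c in x.columns if c != "const" and x[c].nunique() < 2]
        if skipped:
            warnings.warn(f"constant covariates skipped in screening: {skipped}")
        for col in [c for c in x.columns if c != "const" and c not in skipped]:
            xc = x[["const", col]]
            ols = OLS(y, xc).fit()
            med = QuantReg(y, xc).fit(0.5)
            rows.append((col, "ols", ols.params[1] * 100, ols.pvalues()[1]))
            rows.append((col, "qreg_median", med.params[1] * 100, np.nan))
        return pd.DataFrame(rows, columns=["covariate", "method", "estimate", "p"])

    def leverage_flags(self, adjusted: bool = True):
        x, _, _ = self.design(adjusted=adjusted)
        return leverage_flags(x)

    def predicted_curves(
        self, comparison: ComparisonTable, age_grid, races=("NHW", "NHB", "Other"),
        clamp: bool = True,
    ) -> pd.DataFrame:
        """Predicted MPR by age per method / quantile / race, with the
        adjustment covariates held at their reference values."""
        x, _, meta = self.design(adjusted=True)
        center = meta.get("age_center", 66.0)
        age_grid = np.asarray(age_grid, dtype=float)
        amin, amax = self.cohort["age"].min(), self.cohort["age"].max()
        if (age_grid < amin).any() or (age_grid > amax).any():
            warnings.warn("age grid extends beyond the observed age range")
        rows = []
        for (method, tau), fit in comparison.fits.items():
            cols = list(x.columns) if meta.get("adjusted", True) else None
            names = fit.exog_names if hasattr(fit, "exog_names") else cols
            for race in races:
                grid = pd.DataFrame(0.0, index=range(len(age_grid)), columns=names)
                grid["const"] = 1.0
                if race != self.spec.race_ref:
                    col = f"race_{race}"
                    if col not in grid.columns:
                        raise ValueError(f"unseen race category {race!r}")
                    grid[col] = 1.0
                if "age_c" in grid.columns:
                    grid["age_c"] = age_grid - center
                if "age_c2" in grid.columns:
                    grid["age_c2"] = (age_grid - center) ** 2
                pred = fit.predict(grid.to_numpy(dtype=float), clamp=clamp)
                for a, p in zip(age_grid, np.ravel(pred)):
                    rows.append((method, tau, race, a, p))
        return pd.DataFrame(rows, columns=["method", "tau", "race", "age", "mpr"])


def leverage_flags(design: pd.DataFrame, threshold_prob: float = 0.975):
    """Robust leverage-point flags from coordinatewise median/MAD distances.

    Each non-constant column is centered at its median and scaled by its
    normal-consistent MAD; the squared distance summed over usable
    columns is compared with the chi-square(df = #columns) quantile at
    ``threshold_prob``.  Columns with zero MAD (e.g. rare dummies) are
    excluded with a warning.  Flags are reported; observations are never
    removed.

    Returns ``(flags bool array, distances, used_columns)``.
    """
    if isinstance(design, pd.DataFrame):
        cols = [c for c in design.columns if c != "const"]
        x = design[cols].to_numpy(dtype=float)
    else:
        x = np.asarray(design, dtype=float)
        cols = [f"x{j}" for j in range(x.shape[1])]
    n = x.shape[0]
    med = np.median(x, axis=0)
    mad = stats.median_abs_deviation(x, axis=0, scale="normal")
    usable = mad > 0
    if not usable.all():
        excluded = [c for c, u in zip(cols, usable) if not u]
        warnings.warn(f"zero-MAD columns excluded from leverage distance: {excluded}")
    if not usable.any():
        return np.zeros(n, dtype=bool), np.zeros(n), []
    z = (x[:, usable] - med[usable]) / mad[usable]
    d2 = np.sum(z**2, axis=1)
    df = int(usable.sum())
    flags = d2 > stats.chi2.ppf(threshold_prob, df)
    return flags, d2, [c for c, u in zip(cols, usable) if u]
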