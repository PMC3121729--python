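"""Mean-model comparators: homoscedastic OLS and a random-intercept LMM.

Both model the conditional mean of the outcome, in contrast to the
quantile model.  OLS solves the normal equations and reports classical
standard errors together with residual diagnostics (the homoscedasticity
and normality assumptions frequently fail for bounded, skewed outcomes
like possession ratios, so the diagnostics are always attached).  The
mixed model adds a per-subject Gaussian intercept,

    y_ij = x_ij' beta + b_i + e_ij,  b_i ~ N(0, s2_subject),
                                     e_ij ~ N(0, s2_resid),

fitted by maximum likelihood profiled over the variance ratio
lambda = s2_subject / s2_resid (REML available via a flag).  When every
subject contributes a single observation the variance split is not
identifiable; the fit falls back to OLS with a warning and reports
s2_subject as not estimable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .quantreg import _check_rank


@dataclass
class MeanResults:
    """Fixed effects, uncertainties and diagnostics of a mean model.

    ``sigma2_subject`` is NaN for OLS and for the unidentifiable
    singleton-subject LMM fallback.
    """

    method: str
    params: np.ndarray
    bse: np.ndarray
    sigma2_resid: float
    sigma2_subject: float
    loglik: float
    exog_names: list
    nobs: int
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    fallback_ols: bool = False
    model: object = None

    def predict(self, exog, clamp=False):
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[None, :]
        pred = exog @ self.params
        return np.clip(pred, 0.0, 1.0) if clamp else pred

    def tvalues(self):
        return self.params / self.bse

    def pvalues(self):
        df = max(self.nobs - len(self.params), 1)
        return 2.0 * stats.t.sf(np.abs(self.tvalues()), df)

    def conf_int(self, level=0.95):
        df = max(self.nobs - len(self.params), 1)
        q = stats.t.ppf(0.5 + level / 2.0, df)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    def summary(self):
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "term": self.exog_names,
                "estimate": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.pvalues(),
            }
        )
        head = [
            f"{self.method.upper()} fit, n = {self.nobs}",
            f"  sigma2_resid = {self.sigma2_resid:.6g}"
            + (
                f"   sigma2_subject = {self.sigma2_subject:.6g}"
                if np.isfinite(self.sigma2_subject)
                else "   sigma2_subject: not estimable"
            ),
        ]
        if self.diagnostics:
            head.append(f"  diagnostics: {self.diagnostics}")
        return "\n".join(head) + "\n" + tab.to_string(index=False)


def _residual_diagnostics(exog, resid):
    """Breusch-Pagan heteroscedasticity LM test and residual normality."""
    n, p = exog.shape
    u2 = resid**2
    # auxiliary regression of squared residuals on the design
    coef, *_ = linalg.lstsq(exog, u2)
    fitted = exog @ coef
    ss_res = float(np.sum((u2 - fitted) ** 2))
    ss_tot = float(np.sum((u2 - u2.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    lm = n * r2
    df = max(p - 1, 1)
    het_p = float(stats.chi2.sf(lm, df))
    if n >= 20:
        norm_stat, norm_p = stats.normaltest(resid)
    else:
        norm_stat, norm_p = np.nan, np.nan
    return {
        "breusch_pagan_lm": float(lm),
        "breusch_pagan_p": het_p,
        "normality_stat": float(norm_stat),
        "normality_p": float(norm_p),
    }


class OLS:
    """Homoscedastic linear model fitted by the normal equations."""

    def __init__(self, endog, exog, exog_names=None):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns) if exog_names is None else exog_names
            exog = exog.to_numpy(dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        _check_rank(self.exog, self.exog_names)

    def fit(self) -> MeanResults:
        x, y = self.exog, self.endog
        n, p = x.shape
        xtx = x.T @ x
        beta = linalg.solve(xtx, x.T @ y, assume_a="pos")
        resid = y - x @ beta
        dof = n - p
        sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
        cov = sigma2 * linalg.inv(xtx)
        sigma2_mle = float(resid @ resid / n)
        loglik = (
            -0.5 * n * (np.log(2.0 * np.pi * sigma2_mle) + 1.0)
            if sigma2_mle > 0
            else np.inf
        )
        return MeanResults(
            method="ols",
            params=beta,
            bse=np.sqrt(np.diag(cov)),
            sigma2_resid=sigma2,
            sigma2_subject=np.nan,
            loglik=loglik,
            exog_names=self.exog_names,
            nobs=n,
            diagnostics=_residual_diagnostics(x, resid),
            model=self,
        )


class RandomInterceptLM:
    """Linear mixed model with a single random intercept per subject."""

    def __init__(self, endog, exog, groups, exog_names=None):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns) if exog_names is None else exog_names
            exog = exog.to_numpy(dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        _check_rank(self.exog, self.exog_names)
        groups = np.asarray(groups)
        if groups.shape[0] != self.endog.shape[0]:
            raise ValueError("groups must have one entry per observation")
        _, self.group_idx = np.unique(groups, return_inverse=True)
        self.n_groups = int(self.group_idx.max()) + 1

    # -- profiled likelihood machinery ------------------------------------
    def _suffstats(self):
        x, y, g = self.exog, self.endog, self.group_idx
        p = x.shape[1]
        sizes = np.bincount(g, minlength=self.n_groups).astype(float)
        xtx = x.T @ x
        xty = x.T @ y
        yty = float(y @ y)
        # per-group sums of columns and of y
        sx = np.zeros((self.n_groups, p))
        for j in range(p):
            sx[:, j] = np.bincount(g, weights=x[:, j], minlength=self.n_groups)
        sy = np.bincount(g, weights=y, minlength=self.n_groups)
        return sizes, xtx, xty, yty, sx, sy

    def _profile(self, lam, stats_, reml):
        sizes, xtx, xty, yty, sx, sy = stats_
        n, p = self.exog.shape
        c = lam / (1.0 + lam * sizes)  # per-group shrinkage weight
        xvx = xtx - (sx * c[:, None]).T @ sx
        xvy = xty - sx.T @ (c * sy)
        yvy = yty - float(c @ sy**2)
        beta = linalg.solve(xvx, xvy, assume_a="pos")
        q = max(yvy - 2.0 * beta @ xvy + beta @ xvx @ beta, 1e-300)
        logdet_v = float(np.sum(np.log1p(lam * sizes)))
        if reml:
            dof = n - p
            sigma2 = q / dof
            sign, logdet_x = np.linalg.slogdet(xvx)
            ll = -0.5 * (
                dof * np.log(2.0 * np.pi * sigma2) + logdet_v + logdet_x + dof
            )
        else:
            sigma2 = q / n
            ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_v + n)
        return ll, beta, sigma2, xvx

    def fit(self, reml: bool = False) -> MeanResults:
        """ML (default) or REML estimation via the profiled likelihood.

        The scalar profile over lambda = s2_subject / s2_resid is
        maximized by bounded search; lambda = 0 (no between-subject
        variance) is checked explicitly so boundary solutions are exact.
        """
        sizes = np.bincount(self.group_idx, minlength=self.n_groups)
        if sizes.max() < 2:
            warnings.warn(
                "every subject has a single observation; the random-intercept "
                "variance is not identifiable - falling back to OLS fixed effects"
            )
            res = OLS(self.endog, self.exog, exog_names=self.exog_names).fit()
            res.method = "lmm"
            res.fallback_ols = True
            res.model = self
            return res
        stats_ = self._suffstats()

        def neg_ll(log_lam):
            return -self._profile(np.exp(log_lam), stats_, reml)[0]

        opt = optimize.minimize_scalar(
            neg_ll, bounds=(np.log(1e-10), np.log(1e6)), method="bounded",
            options={"xatol": 1e-10},
        )
        lam_hat = float(np.exp(opt.x))
        ll_hat = -float(opt.fun)
        ll0 = self._profile(0.0, stats_, reml)[0]
        if ll0 >= ll_hat - 1e-10:
            lam_hat, ll_hat = 0.0, ll0
        ll, beta, sigma2, xvx = self._profile(lam_hat, stats_, reml)
        cov = sigma2 * linalg.inv(xvx)
        resid = self.endog - self.exog @ beta
        return MeanResults(
            method="lmm",
            params=beta,
            bse=np.sqrt(np.diag(cov)),
            sigma2_resid=float(sigma2),
            sigma2_subject=float(lam_hat * sigma2),
            loglik=float(ll),
            exog_names=self.exog_names,
            nobs=self.endog.shape[0],
            diagnostics=_residual_diagnostics(self.exog, resid),
            converged=bool(opt.success or lam_hat == 0.0),
            model=self,
        )


def fit_ols(endog, exog, exog_names=None) -> MeanResults:
    return OLS(endog, exog, exog_names=exog_names).fit()


def fit_lmm(endog, exog, groups, exog_names=None, reml: bool = False) -> MeanResults:
    return RandomInterceptLM(endog, exog, groups, exog_names=exog_names).fit(reml=reml)
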