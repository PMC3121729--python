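"""Linear quantile regression by check-loss minimization.

The conditional quantile model is ``Q_y(tau | x) = x' beta_tau``; the
estimator minimizes the check (pinball) loss

    sum_i rho_tau(y_i - x_i' beta),   rho_tau(r) = r * (tau - 1[r < 0]),

a convex piecewise-linear objective.  The solver smooths the kink of the
check function with a quadratic of half-width gamma (finite smoothing), so
damped Newton-Raphson steps can be taken, and shrinks gamma geometrically
until the smoothed problem is indistinguishable from the exact one.  A
final vertex polish solves the interpolation system through the p
observations with the smallest residuals, which recovers the exact
piecewise-linear optimum (an optimal solution always passes through p data
points when the design has full rank).

``exact_small_fit`` enumerates every p-subset of observations and is the
brute-force oracle for small instances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import linalg


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix does not have full column rank."""


def check_loss(residual, tau):
    """Check (pinball) loss rho_tau(r) = r * (tau - 1[r < 0]).

    Piecewise linear with slope ``tau`` for positive residuals and
    ``tau - 1`` for negative ones; zero only at ``r = 0``.  At tau = 0.5
    this is |r| / 2, i.e. median regression.  Vectorized over ``residual``.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    r = np.asarray(residual, dtype=float)
    out = r * (tau - (r < 0))
    return out if out.ndim else float(out)


def objective_value(beta, exog, endog, tau):
    """Exact check-loss objective sum_i rho_tau(y_i - x_i' beta)."""
    exog = np.asarray(exog, dtype=float)
    endog = np.asarray(endog, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if exog.shape[1] != beta.shape[0] or exog.shape[0] != endog.shape[0]:
        raise ValueError(
            f"dimension mismatch: X {exog.shape}, y {endog.shape}, beta {beta.shape}"
        )
    return float(np.sum(check_loss(endog - exog @ beta, tau)))


def _check_rank(exog, names):
    """QR with column pivoting; raise naming the dependent columns."""
    n, p = exog.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    _, r, piv = linalg.qr(exog, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"linearly dependent columns: {bad}"
        )


def _smoothed(r, tau, gamma, w):
    """Weighted smoothed loss value, per-row derivative psi, in-band mask.

    Quadratic r^2/(4 gamma) + (tau - 1/2) r + gamma/4 on |r| <= gamma,
    matching the check loss and its slope at +-gamma.  Weights let
    duplicated observations (bootstrap resamples) collapse to one row.
    """
    band = np.abs(r) <= gamma
    pos = r > gamma
    loss = np.where(pos, tau * r, (tau - 1.0) * r)
    rb = r[band]
    loss[band] = rb * rb / (4.0 * gamma) + (tau - 0.5) * rb + gamma / 4.0
    psi = np.where(pos, tau, tau - 1.0)
    psi[band] = rb / (2.0 * gamma) + tau - 0.5
    return float(w @ loss), psi, band


def _wobj(exog, endog, w, tau, beta):
    return float(w @ check_loss(endog - exog @ beta, tau))


@dataclass
class QuantRegResults:
    """Fit of one conditional quantile.

    Attributes
    ----------
    tau : quantile level actually fitted (possibly clipped away from 0/1)
    params : coefficient vector minimizing the check loss
    objective : exact check-loss value at ``params``
    iterations : total Newton iterations across the smoothing schedule
    converged : whether the optimality certificate held at the solution
    gamma_final : last smoothing half-width used
    ci : per-coefficient (low, high) intervals once ``bootstrap_ci`` ran
    """

    model: "QuantReg"
    tau: float
    params: np.ndarray
    objective: float
    iterations: int
    converged: bool
    gamma_final: float
    ci: pd.DataFrame | None = field(default=None, repr=False)
    ci_method: str | None = None

    @property
    def exog_names(self):
        return self.model.exog_names

    def resid(self):
        return self.model.endog - self.model.exog @ self.params

    def predict(self, exog=None, clamp=False):
        """Predicted tau-th conditional quantile x' beta_tau.

        With ``clamp=True`` predictions are truncated to [0, 1] (for
        possession-ratio reporting); the flag is recorded on the result.
        """
        if exog is None:
            exog = self.model.exog
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[None, :]
        if exog.shape[1] != self.params.shape[0]:
            raise ValueError(
                f"exog has {exog.shape[1]} columns, fit has {self.params.shape[0]}"
            )
        pred = exog @ self.params
        if clamp:
            pred = np.clip(pred, 0.0, 1.0)
        self._last_predict_clamped = bool(clamp)
        return pred

    def bootstrap_ci(self, n_boot=500, seed=0, level=0.95):
        """xy-pair bootstrap percentile intervals for the coefficients.

        Whole observations (x_i, y_i) are resampled with replacement and
        the model refit per replicate; the interval per coefficient is the
        exact empirical percentile pair (order-statistic definition, no
        interpolation).  Rank-deficient resamples are redrawn and logged.
        Deterministic given ``seed``.  Also attaches a two-sided percentile
        p-value (smallest level whose interval excludes 0).
        """
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        m = self.model
        n, p = m.exog.shape
        rng = default_rng(seed)
        est = np.empty((n_boot, p))
        redraws = 0
        for b in range(n_boot):
            for _attempt in range(100):
                idx = rng.integers(0, n, n)
                wts = np.bincount(idx, minlength=n).astype(float)
                keep = wts > 0
                xb, yb = m.exog[keep], m.endog[keep]
                try:
                    _check_rank(xb, m.exog_names)
                except (RankDeficientError, ValueError):
                    redraws += 1
                    continue
                fit = _fit_smoothed(
                    xb, yb, self.tau, weights=wts[keep],
                    start_params=self.params,
                    gamma0=max(10.0 * _GAMMA_MIN, 1e-4 * m._scale),
                )
                est[b] = fit[0]
                break
            else:  # pragma: no cover - pathological designs only
                raise RuntimeError("could not draw a full-rank bootstrap resample")
        if redraws:
            warnings.warn(f"redrew {redraws} rank-deficient bootstrap resamples")
        alpha = 1.0 - level
        lo = _exact_percentile(est, alpha / 2.0)
        hi = _exact_percentile(est, 1.0 - alpha / 2.0)
        pvals = np.array(
            [2.0 * min(np.mean(est[:, j] <= 0), np.mean(est[:, j] >= 0)) for j in range(p)]
        )
        pvals = np.minimum(pvals, 1.0)
        self.ci = pd.DataFrame(
            {
                "term": m.exog_names,
                "estimate": self.params,
                "ci_low": lo,
                "ci_high": hi,
                "p": pvals,
                "se_boot": est.std(axis=0, ddof=1),
            }
        )
        self.ci_method = f"xy-pair percentile bootstrap (B={n_boot}, level={level})"
        self._boot_estimates = est
        return self.ci

    def summary(self):
        lines = [
            "Quantile regression (check-loss minimization)",
            f"  tau = {self.tau:.4g}   n = {self.model.exog.shape[0]}   "
            f"p = {self.model.exog.shape[1]}",
            f"  objective = {self.objective:.6g}   iterations = {self.iterations}"
            f"   converged = {self.converged}",
        ]
        if self.ci is not None:
            lines.append(f"  CI method: {self.ci_method}")
            lines.append(self.ci.to_string(index=False))
        else:
            tab = pd.DataFrame({"term": self.exog_names, "estimate": self.params})
            lines.append(tab.to_string(index=False))
        return "\n".join(lines)


def _exact_percentile(a, prob, axis=0):
    """Exact empirical percentile: smallest value with ECDF >= prob."""
    a = np.sort(np.asarray(a, dtype=float), axis=axis)
    n = a.shape[axis]
    k = max(int(np.ceil(n * prob)), 1) - 1
    return np.take(a, min(k, n - 1), axis=axis)


_GAMMA_MIN = 1e-8


def _exact_line_search(r, a, tau, w):
    """Minimizer of t -> sum_i w_i rho_tau(r_i - t a_i).

    The objective is convex piecewise linear in t with kinks at
    t_i = r_i / a_i; its right derivative increases by w_i |a_i| at each
    kink, so the minimizer is the first kink where the cumulative
    derivative becomes nonnegative (a weighted-median computation).
    """
    mask = a != 0.0
    if not mask.any():
        return 0.0
    rv, av, wv = r[mask], a[mask], w[mask]
    wa = wv * av
    t_i = rv / av
    order = np.argsort(t_i, kind="stable")
    ts = t_i[order]
    base = -tau * wa.sum() + wa[wa < 0.0].sum()  # right derivative below all kinks
    cum = base + np.cumsum(np.abs(wa)[order])
    k = int(np.searchsorted(cum, 0.0, side="left"))
    return float(ts[min(k, ts.size - 1)])


def _newton_continuation(exog, endog, w, tau, beta, gamma0, gamma_min, shrink,
                         max_iter):
    """Newton directions on the smoothed objective over a geometric gamma
    schedule, with exact line search on the true check loss.

    Returns (beta, iterations, gamma_final).
    """
    n, p = exog.shape
    total_iter = 0
    gamma = gamma0
    eye = np.eye(p)
    obj = _wobj(exog, endog, w, tau, beta)
    obj_tol = 1e-13 * max(1.0, obj)
    wsum = float(w.sum())
    while True:
        for _ in range(max_iter):
            r = endog - exog @ beta
            _, psi, band = _smoothed(r, tau, gamma, w)
            g = -(exog.T @ (w * psi))
            if np.abs(g).max() <= 1e-9 * wsum:
                break
            step = None
            if int(band.sum()) >= p:
                xb = exog[band]
                h = (xb.T @ (xb * w[band, None])) / (2.0 * gamma)
                tr = np.trace(h) / p
                ridge = 0.0
                for _k in range(4):
                    try:
                        cand = np.linalg.solve(h + ridge * eye, -g)
                    except np.linalg.LinAlgError:
                        cand = None
                    if cand is not None and np.isfinite(cand).all() and g @ cand < 0:
                        step = cand
                        break
                    ridge = tr * 1e-8 if ridge == 0.0 else ridge * 1e4
            if step is None:
                step = -g  # subgradient direction; the line search sets the scale
            t = _exact_line_search(r, exog @ step, tau, w)
            total_iter += 1
            if t == 0.0:
                break
            cand = beta + t * step
            new_obj = _wobj(exog, endog, w, tau, cand)
            if new_obj <= obj - obj_tol:
                beta, obj = cand, new_obj
            else:
                break
        if gamma <= gamma_min:
            break
        gamma = max(gamma * shrink, gamma_min)
    return beta, total_iter, gamma


def _vertex_polish(exog, endog, w, tau, beta, rounds=10):
    """Iterated exact polish: an optimal solution interpolates p
    observations, so repeatedly solve the interpolation systems through
    the smallest-residual rows and keep any strict improvement."""
    n, p = exog.shape
    extra = 4 if p <= 4 else (3 if p <= 12 else 2)
    obj = _wobj(exog, endog, w, tau, beta)
    for _ in range(rounds):
        r = endog - exog @ beta
        pool = np.argsort(np.abs(r))[: min(n, p + extra)]
        subsets = np.array(list(itertools.combinations(pool, p)))
        a = exog[subsets]  # (m, p, p)
        b = endog[subsets]  # (m, p)
        with np.errstate(all="ignore"):
            try:
                cands = np.linalg.solve(a, b[..., None])[..., 0]
            except np.linalg.LinAlgError:
                cands = np.full((len(subsets), p), np.nan)
                for j, s in enumerate(subsets):
                    try:
                        cands[j] = np.linalg.solve(exog[s], endog[s])
                    except np.linalg.LinAlgError:
                        pass
            resid = endog[None, :] - cands @ exog.T
            objs = check_loss(resid, tau) @ w
        objs[~np.isfinite(objs)] = np.inf
        j = int(np.argmin(objs))
        if objs[j] < obj * (1.0 - 1e-14) - 1e-300:
            beta, obj = cands[j], float(objs[j])
        else:
            if objs[j] <= obj:
                beta, obj = cands[j], float(objs[j])  # prefer a vertex at ties
            break
    return beta, obj


def _certify_optimal(exog, endog, w, tau, beta, tol_r, box_tol=1e-7):
    """Exact subgradient optimality check.

    beta minimizes the weighted check loss iff there are dual weights
    xi_i in [w_i (tau-1), w_i tau] on the zero-residual rows with
    sum_active x_i xi_i = -sum_inactive x_i w_i psi_i,
    psi_i = tau - 1[r_i < 0].
    """
    r = endog - exog @ beta
    active = np.abs(r) <= tol_r
    psi = np.where(r > 0, tau, tau - 1.0)
    v = exog[~active].T @ (w[~active] * psi[~active])
    m = int(active.sum())
    scale = box_tol * max(1.0, float(np.abs(v).max()) if v.size else 1.0)
    if m == 0:
        return bool(np.abs(v).max() <= scale) if v.size else True
    xa = exog[active]
    wa = w[active]
    lo, hi = wa * (tau - 1.0), wa * tau
    if m <= exog.shape[1]:
        xi, *_ = np.linalg.lstsq(xa.T, -v, rcond=None)
        ok = np.abs(xa.T @ xi + v).max() <= scale
        slack = box_tol * max(1.0, float(wa.max()))
        return bool(ok and (xi >= lo - slack).all() and (xi <= hi + slack).all())
    from scipy.optimize import linprog

    lp = linprog(
        np.zeros(m), A_eq=xa.T, b_eq=-v,
        bounds=list(zip(lo, hi)), method="highs",
    )
    return bool(lp.status == 0)


def _edge_descent(exog, endog, w, tau, beta, max_rounds=200):
    """Certified finisher for the piecewise-linear objective.

    The objective is an LP; a solution interpolates p observations.
    Away from a vertex, move inside the null space of the active rows
    (strict descent if available, otherwise a flat move that grows the
    active set); at a vertex, relax one active row at a time and walk
    any descending edge, each move priced by exact line search.  Stop as
    soon as the exact subgradient certificate holds.

    Returns (beta, certified_optimal).
    """
    n, p = exog.shape
    tol_r = 1e-9 * max(1.0, float(np.abs(endog).max()))
    obj = _wobj(exog, endog, w, tau, beta)
    obj_tol = 1e-12 * max(1.0, obj)
    der_tol = 1e-10 * max(1.0, float(w.sum()))
    flat_streak = 0
    for _ in range(max_rounds):
        r = endog - exog @ beta
        act_mask = np.abs(r) <= tol_r
        active = np.where(act_mask)[0]
        m = active.size
        # candidate direction matrix (p x k)
        dmat = None
        if m == p:
            try:
                dmat = np.linalg.inv(exog[active])  # columns: edge directions
            except np.linalg.LinAlgError:
                dmat = None
        if dmat is None:
            if m < p:
                dmat = linalg.null_space(exog[active]) if m else np.eye(p)
            else:  # degenerate vertex: relax one active row at a time
                cols = []
                for j in active:
                    rest = active[active != j]
                    ns = linalg.null_space(exog[rest]) if rest.size else np.eye(p)
                    if ns.size:
                        cols.append(ns)
                dmat = np.hstack(cols) if cols else None
        if dmat is None or dmat.size == 0:
            return beta, _certify_optimal(exog, endog, w, tau, beta, tol_r)
        amat = exog @ dmat  # (n, k)
        # one-sided directional derivatives: inactive rows contribute the
        # fixed slope -w psi a, active rows the kink penalty
        psi_w = w * np.where(r > 0, tau, tau - 1.0)
        s_in = amat[~act_mask].T @ psi_w[~act_mask]
        a_act, w_act = amat[act_mask], w[act_mask]
        pen_pos = ((1.0 - tau) * np.maximum(a_act, 0.0)
                   + tau * np.maximum(-a_act, 0.0)).T @ w_act
        pen_neg = ((1.0 - tau) * np.maximum(-a_act, 0.0)
                   + tau * np.maximum(a_act, 0.0)).T @ w_act
        der_pos = -s_in + pen_pos
        der_neg = s_in + pen_neg
        der = np.concatenate([der_pos, der_neg])
        j = int(np.argmin(der))
        if der[j] < -der_tol:
            k = dmat.shape[1]
            sgn = 1.0 if j < k else -1.0
            col = j if j < k else j - k
            a = sgn * amat[:, col]
            t = _exact_line_search(r, a, tau, w)
            if t > 0.0:
                cand = beta + (sgn * t) * dmat[:, col]
                new_obj = _wobj(exog, endog, w, tau, cand)
                if new_obj < obj - obj_tol:
                    beta, obj = cand, new_obj
                    flat_streak = 0
                    continue
            return beta, _certify_optimal(exog, endog, w, tau, beta, tol_r)
        if _certify_optimal(exog, endog, w, tau, beta, tol_r):
            return beta, True
        if m < p and flat_streak < p + 1:
            # zero in-subspace gradient but not yet optimal: ride a flat
            # direction to a point with a larger active set
            a = amat[:, 0]
            t = _exact_line_search(r, a, tau, w)
            if t == 0.0:
                t = _exact_line_search(r, -a, tau, w)
                a, sgn = -a, -1.0
            else:
                sgn = 1.0
            if t > 0.0:
                cand = beta + (sgn * t) * dmat[:, 0]
                if (np.abs(endog - exog @ cand) <= tol_r).sum() > m:
                    beta = cand
                    obj = _wobj(exog, endog, w, tau, beta)
                    flat_streak += 1
                    continue
        return beta, False
    return beta, False


def _dedupe(exog, endog):
    """Collapse duplicated (x, y) rows into weights.

    Bootstrap resamples repeat observations; fitting the weighted
    problem on unique rows keeps the solution polytope non-degenerate.
    """
    n = exog.shape[0]
    rows = np.column_stack([exog, endog])
    uniq, counts = np.unique(rows, axis=0, return_counts=True)
    if uniq.shape[0] == n:
        return exog, endog, np.ones(n)
    return (
        np.ascontiguousarray(uniq[:, :-1]),
        np.ascontiguousarray(uniq[:, -1]),
        counts.astype(float),
    )


def _fit_smoothed(exog, endog, tau, weights=None, start_params=None, gamma0=None,
                  gamma_min=_GAMMA_MIN, shrink=0.1, max_iter=15, tol=1e-10):
    """Finite-smoothing Newton solve + vertex polish + certified edge descent.

    Duplicated observations are collapsed into weights first (callers
    that already hold multiplicities pass them as ``weights``).  Returns
    (beta, total_iterations, converged, gamma_final).
    """
    if weights is None:
        exog, endog, w = _dedupe(exog, endog)
    else:
        w = np.asarray(weights, dtype=float)
    n, p = exog.shape
    scale = float(np.median(np.abs(endog - endog.mean())))
    default_gamma0 = scale if scale > 0 else max(float(np.std(endog)), 1e-3)
    g0 = max(gamma0 if gamma0 is not None else default_gamma0, gamma_min)

    if start_params is None:
        beta0, *_ = linalg.lstsq(exog, endog)
    else:
        beta0 = np.asarray(start_params, dtype=float).copy()

    beta, total_iter, gamma = _newton_continuation(
        exog, endog, w, tau, beta0, g0, gamma_min, shrink, max_iter
    )
    if p <= 8:  # subset enumeration is cheap only at small p
        beta, _obj = _vertex_polish(exog, endog, w, tau, beta)
    beta, certified = _edge_descent(exog, endog, w, tau, beta)
    converged = certified and _subgradient_ok(endog - exog @ beta, tau, p, w=w)
    return beta, total_iter, converged, gamma


def _subgradient_ok(resid, tau, p, w=None, tol=1e-8):
    """Count certificate: #{r<0} <= n*tau <= #{r<=0} + p (weighted form)."""
    if w is None:
        w = np.ones(resid.size)
    wsum = float(w.sum())
    w_neg = float(w[resid < -tol].sum())
    w_nonpos = float(w[resid <= tol].sum())
    slack = p * float(w.max()) if w.size else p
    return w_neg <= wsum * tau + 1e-9 and wsum * tau <= w_nonpos + slack + 1e-9


class QuantReg:
    """Quantile regression model for a response and design matrix.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (any real values; for possession ratios, proportions).
    exog : array-like or DataFrame, shape (n, p)
        Design matrix including the constant column.
    exog_names : optional list of column names (taken from a DataFrame).

    The design must have full column rank; deficiency raises
    ``RankDeficientError`` naming the dependent columns.
    """

    def __init__(self, endog, exog, exog_names=None):
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns) if exog_names is None else exog_names
            exog = exog.to_numpy(dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if np.isnan(self.exog).any() or np.isnan(self.endog).any():
            raise ValueError("missing values in the design or response")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        _check_rank(self.exog, self.exog_names)
        self._scale = float(np.median(np.abs(self.endog - self.endog.mean()))) or 1.0

    def _clip_tau(self, tau):
        n = self.endog.shape[0]
        lo, hi = 0.5 / n, 1.0 - 0.5 / n
        if not 0.0 < tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {tau}")
        if tau < lo or tau > hi:
            clipped = float(np.clip(tau, lo, hi))
            warnings.warn(
                f"tau={tau} is inside the extreme-order-statistic zone for n={n}; "
                f"clipped to {clipped}"
            )
            return clipped
        return float(tau)

    def fit(self, tau, start_params=None, gamma0=None, max_iter=15, tol=1e-10):
        """Minimize the check loss at level ``tau``.

        Smoothed-Newton continuation (geometric gamma schedule, default
        gamma_0 = median |y - ybar| shrunk x0.1 down to 1e-10) followed by
        an exact vertex polish.  Non-convergence is reported through
        ``converged=False``, never silently.
        """
        tau = self._clip_tau(tau)
        beta, iters, converged, gamma = _fit_smoothed(
            self.exog, self.endog, tau,
            start_params=start_params, gamma0=gamma0, max_iter=max_iter, tol=tol,
        )
        obj = objective_value(beta, self.exog, self.endog, tau)
        if not converged:
            warnings.warn(f"quantile fit at tau={tau} did not certify optimality")
        return QuantRegResults(
            model=self, tau=tau, params=beta, objective=obj,
            iterations=iters, converged=converged, gamma_final=gamma,
        )

    def fit_exact(self, tau, max_n=12, max_p=3):
        """Globally optimal fit by exhaustive p-subset enumeration.

        An optimal check-loss solution interpolates p observations, so
        enumerating all p-subsets, solving each interpolation system, and
        keeping the feasible fit with minimal objective is exact.  Refuses
        instances beyond (max_n, max_p) - combinatorial blow-up.
        """
        n, p = self.exog.shape
        if n > max_n or p > max_p:
            raise ValueError(
                f"exact enumeration refused: n={n} > {max_n} or p={p} > {max_p}"
            )
        tau = self._clip_tau(tau)
        best_beta, best_obj = None, np.inf
        for subset in itertools.combinations(range(n), p):
            a = self.exog[list(subset)]
            try:
                cand = linalg.solve(a, self.endog[list(subset)])
            except np.linalg.LinAlgError:
                continue
            if not np.isfinite(cand).all():
                continue
            o = objective_value(cand, self.exog, self.endog, tau)
            if o < best_obj:
                best_beta, best_obj = cand, o
        if best_beta is None:
            raise RankDeficientError("no nonsingular p-subset of observations")
        return QuantRegResults(
            model=self, tau=tau, params=best_beta, objective=best_obj,
            iterations=0, converged=True, gamma_final=0.0,
        )


def exact_small_fit(exog, endog, tau, max_n=12, max_p=3, exog_names=None):
    """Module-level convenience wrapper around ``QuantReg.fit_exact``."""
    return QuantReg(endog, exog, exog_names=exog_names).fit_exact(
        tau, max_n=max_n, max_p=max_p
    )
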