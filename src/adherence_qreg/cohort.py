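"""Synthetic cohorts with a planted conditional-quantile structure.

Covariate tables mimic a VA-style type-2-diabetes cohort (race/ethnicity,
sex, age, marital status, employment, five medical and six psychiatric
comorbidity flags, a poor-glycemic-control flag).  Outcomes are generated
by inverse-transform sampling of a user-specified conditional quantile
function: draw U ~ Uniform(0, 1) and set

    Y = clamp( x' beta(U) + b_subject , 0, 1 ),

so beta(tau) is the literal estimand of quantile regression at every tau
(no additive-error approximation).  ``generate_refill_records`` emits a
refill history whose engine-computed MPR equals any target ratio, closing
the loop with :mod:`adherence_qreg.mpr`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .mpr import DEFAULT_WINDOW_DAYS


class ConfigError(ValueError):
    """Invalid generator configuration."""


# Binary covariate prevalences of the emulated cohort (proportions of the
# full sample): sex plus five medical and six psychiatric comorbidities
# and the poor-glycemic-control (HbA1c > 8%) flag.
TABLE1_PREVALENCES: dict[str, float] = {
    "male": 0.973,
    "cancer": 0.050,
    "chd": 0.139,
    "chf": 0.080,
    "hypertension": 0.257,
    "stroke": 0.030,
    "poor_hba1c": 0.116,
    "bipolar": 0.019,
    "gad": 0.022,
    "mdd": 0.078,
    "ptsd": 0.051,
    "psychotic": 0.024,
    "substance_use": 0.144,
}

RACE_LEVELS = ("NHW", "NHB", "Other")
MARITAL_LEVELS = ("married", "divorced", "never_married")
EMPLOYMENT_LEVELS = ("unemployed", "retired", "employed")

BINARY_COVARIATES = tuple(TABLE1_PREVALENCES)


def _normalized(probs: Mapping[str, float], levels: Sequence[str], what: str):
    vec = np.array([float(probs[k]) for k in levels])
    if (vec < 0).any() or (vec > 1).any():
        raise ConfigError(f"{what} probabilities must lie in [0, 1]: {probs}")
    s = vec.sum()
    if abs(s - 1.0) > 0.01:
        raise ConfigError(f"{what} probabilities sum to {s}, expected 1")
    return vec / s


@dataclass
class CohortConfig:
    """Parameters of the synthetic covariate generator.

    Race probabilities are over the observed levels {NHW, NHB, Other};
    race is then masked missing-completely-at-random at
    ``missing_race_rate`` (missing is folded into "Other" at encoding
    time).  ``periods_per_patient > 1`` produces repeated measures;
    ``subject_sd`` is the SD of the latent per-patient shift used in that
    mode (the random-intercept truth for mixed-model testing).
    """

    n_patients: int
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: {"NHW": 0.515, "NHB": 0.297, "Other": 0.188}
    )
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE1_PREVALENCES)
    )
    marital_probs: Mapping[str, float] = field(
        default_factory=lambda: {"married": 0.652, "divorced": 0.286, "never_married": 0.062}
    )
    employment_probs: Mapping[str, float] = field(
        default_factory=lambda: {"unemployed": 0.482, "retired": 0.308, "employed": 0.208}
    )
    age_mean: float = 66.0
    age_sd: float = 11.6
    missing_race_rate: float = 0.086
    periods_per_patient: int = 1
    subject_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.periods_per_patient < 1:
            raise ConfigError("periods_per_patient must be >= 1")
        rp = np.array([self.race_probs.get(k, 0.0) for k in RACE_LEVELS], dtype=float)
        if (rp < 0).any() or (rp > 1).any():
            raise ConfigError(f"race_probs must lie in [0, 1]: {self.race_probs}")
        if abs(rp.sum() - 1.0) > 1e-12:
            raise ConfigError(f"race_probs must sum to 1, got {rp.sum()!r}")
        if not 0.0 <= self.missing_race_rate <= 1.0:
            raise ConfigError("missing_race_rate must lie in [0, 1]")
        for name, p in self.covariate_prevalences.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ConfigError(f"prevalence of {name!r} is {p}, outside [0, 1]")
        if self.age_sd < 0 or self.subject_sd < 0:
            raise ConfigError("age_sd and subject_sd must be nonnegative")


def generate_covariates(config: CohortConfig) -> pd.DataFrame:
    """Sample a cohort covariate table; deterministic given ``config.seed``.

    Columns: patient_id, race (NaN where missing), each binary flag,
    marital, employment, age.
    """
    rng = default_rng(config.seed)
    n = config.n_patients
    race_p = _normalized(config.race_probs, RACE_LEVELS, "race")
    race = rng.choice(RACE_LEVELS, size=n, p=race_p).astype(object)
    race[rng.random(n) < config.missing_race_rate] = np.nan
    df = pd.DataFrame({"patient_id": np.arange(n), "race": race})
    for name in config.covariate_prevalences:
        df[name] = (rng.random(n) < float(config.covariate_prevalences[name])).astype(int)
    df["marital"] = rng.choice(
        MARITAL_LEVELS, size=n, p=_normalized(config.marital_probs, MARITAL_LEVELS, "marital")
    )
    df["employment"] = rng.choice(
        EMPLOYMENT_LEVELS,
        size=n,
        p=_normalized(config.employment_probs, EMPLOYMENT_LEVELS, "employment"),
    )
    df["age"] = np.round(rng.normal(config.age_mean, config.age_sd, size=n), 1)
    return df


Curve = Callable[[np.ndarray], np.ndarray]


def _as_curve(spec) -> Curve:
    if callable(spec):
        return spec
    taus, values = spec
    taus = np.asarray(taus, dtype=float)
    values = np.asarray(values, dtype=float)
    if taus.ndim != 1 or taus.shape != values.shape or (np.diff(taus) <= 0).any():
        raise ConfigError("knot curve must be (increasing taus, values) of equal length")
    return lambda u: np.interp(u, taus, values)


@dataclass
class QuantileCoefficientFunction:
    """Per-covariate coefficient curves beta_j(tau) on (0, 1).

    Each curve is a callable tau -> value or a ``(taus, values)`` knot
    pair (piecewise-linear interpolation, flat extrapolation).  Effects
    are keyed by latent-feature name (see ``latent_features``).  For every
    covariate profile x in the generator's support, x' beta(tau) must be
    non-decreasing in tau; ``validate`` checks this on a tau grid and a
    violation is a configuration error.
    """

    intercept: object
    effects: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self._intercept = _as_curve(self.intercept)
        self._effects = {k: _as_curve(v) for k, v in self.effects.items()}

    def linear_predictor(self, features: pd.DataFrame, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.broadcast_to(self._intercept(u), u.shape).astype(float).copy()
        for name, curve in self._effects.items():
            if name not in features.columns:
                raise ConfigError(f"qcf effect {name!r} has no matching feature column")
            out += features[name].to_numpy(dtype=float) * np.broadcast_to(curve(u), u.shape)
        return out

    def validate(self, features: pd.DataFrame, grid: np.ndarray | None = None) -> None:
        """Raise ``ConfigError`` naming the offending profile and tau pair
        if x' beta(tau) decreases anywhere on the grid."""
        if grid is None:
            grid = np.linspace(0.01, 0.99, 50)
        cols = [c for c in self._effects if c in features.columns]
        n = len(features)
        prev = None
        for k, t in enumerate(grid):
            vals = self.linear_predictor(features, np.full(n, float(t)))
            if prev is not None:
                bad = np.where(vals - prev < -1e-9)[0]
                if bad.size:
                    i = int(bad[0])
                    profile = {c: features.iloc[i][c] for c in cols}
                    raise ConfigError(
                        f"x'beta(tau) decreases for profile {profile} between "
                        f"tau={grid[k - 1]:.3f} and tau={grid[k]:.3f} "
                        f"({prev[i]:.6f} -> {vals[i]:.6f})"
                    )
            prev = vals


def latent_features(cohort: pd.DataFrame, age_center: float = 66.0) -> pd.DataFrame:
    """Numeric features the quantile coefficient curves act on.

    Race is treatment-coded against NHW with missing folded into Other;
    age is centered (years) and squared.  Column set: race_NHB,
    race_Other, male, age_c, age_c2, marital/employment dummies, and each
    binary flag present in the cohort table.
    """
    out = pd.DataFrame(index=cohort.index)
    race = cohort["race"].fillna("Other")
    out["race_NHB"] = (race == "NHB").astype(float)
    out["race_Other"] = (race == "Other").astype(float)
    out["age_c"] = cohort["age"].astype(float) - age_center
    out["age_c2"] = out["age_c"] ** 2
    if "marital" in cohort:
        out["never_married"] = (cohort["marital"] == "never_married").astype(float)
        out["divorced"] = (cohort["marital"] == "divorced").astype(float)
    if "employment" in cohort:
        out["employed"] = (cohort["employment"] == "employed").astype(float)
        out["retired"] = (cohort["employment"] == "retired").astype(float)
    for name in BINARY_COVARIATES:
        if name in cohort:
            out[name] = cohort[name].astype(float)
    return out


def generate_mpr(
    cohort: pd.DataFrame,
    qcf: QuantileCoefficientFunction,
    seed: int = 0,
    periods_per_patient: int = 1,
    subject_sd: float = 0.0,
    age_center: float = 66.0,
    clamp: bool = True,
    validate: bool = True,
) -> pd.DataFrame:
    """Draw MPR outcomes by inverting the planted conditional quantile function.

    One row per patient (or per patient x period when
    ``periods_per_patient > 1``, with a patient-level Gaussian shift of SD
    ``subject_sd`` added on the latent scale before clamping).  Returns a
    long table (patient_id, period, mpr).  Deterministic given ``seed``.
    """
    feats = latent_features(cohort, age_center=age_center)
    if validate:
        qcf.validate(feats)
    rng = default_rng(seed)
    n = len(cohort)
    k = int(periods_per_patient)
    shift = rng.normal(0.0, subject_sd, size=n) if subject_sd > 0 else np.zeros(n)
    rows = []
    for period in range(k):
        u = rng.uniform(0.0, 1.0, size=n)
        y = qcf.linear_predictor(feats, u) + shift
        if clamp:
            y = np.clip(y, 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": cohort["patient_id"].to_numpy(),
                    "period": period,
                    "mpr": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["patient_id", "period"], kind="stable", ignore_index=True
    )


def generate_refill_records(
    patient_ids: Sequence,
    target_mpr: Sequence[float],
    n_windows: int = 4,
    window_len: int = DEFAULT_WINDOW_DAYS,
    start_date: str = "2001-01-01",
    drug_class: str = "HS501",
    seed: int | None = None,  # construction is deterministic; kept for API symmetry
) -> pd.DataFrame:
    """Refill histories whose computed MPR matches each target ratio.

    The denominator is pinned to ``n_windows * window_len`` eligible days
    and the supplied total is ``round(target * n_windows * window_len)``
    (clamped to the representable range), so the MPR engine recovers the
    nearest representable day-count ratio.  Full adherence yields one
    ``window_len``-day fill per window; otherwise a bulk fill at the first
    window start plus a 1-day fill ending at follow-up end pin the window
    structure.  Targets below 2 supplied days round up to the smallest
    achievable history (at least one anchoring fill at each end).
    """
    target = np.asarray(target_mpr, dtype=float)
    if ((target < 0) | (target > 1)).any():
        raise ValueError("target MPR values must lie in [0, 1]")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    t0 = pd.Timestamp(start_date)
    total = n_windows * window_len
    rows = []
    for pid, m in zip(patient_ids, target):
        supplied = int(np.clip(round(m * total), 2, total))
        if supplied == total:
            for w in range(n_windows):
                rows.append((pid, drug_class, t0 + pd.Timedelta(days=w * window_len), window_len))
        elif supplied >= window_len + 1:
            # last window filled to capacity pins the inactivity date
            rows.append((pid, drug_class, t0, supplied - window_len))
            rows.append(
                (pid, drug_class, t0 + pd.Timedelta(days=(n_windows - 1) * window_len), window_len)
            )
        else:
            rows.append((pid, drug_class, t0, supplied - 1))
            rows.append((pid, drug_class, t0 + pd.Timedelta(days=total - 1), 1))
    df = pd.DataFrame(rows, columns=["patient_id", "drug_class", "fill_date", "days_supplied"])
    df["fill_date"] = df["fill_date"].dt.strftime("%Y-%m-%d")
    return df


# ---------------------------------------------------------------------------
# presets

def table1_like_config(n_patients: int = 10_000, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort configuration mirroring the emulated sample's prevalences."""
    return CohortConfig(n_patients=n_patients, seed=seed, **overrides)


def shrinking_race_effect(low: float = -0.15, tau_low: float = 0.1, tau_high: float = 0.9):
    """Race coefficient curve shrinking linearly from ``low`` at
    ``tau_low`` to 0 at ``tau_high`` (flat outside)."""
    def curve(u):
        u = np.asarray(u, dtype=float)
        return np.clip(low * (tau_high - u) / (tau_high - tau_low), min(low, 0.0), 0.0)

    return curve


def table1_like_qcf() -> QuantileCoefficientFunction:
    """Convenience preset: left-skewed bounded MPR with median near 0.97
    (reference profile) and a race disparity that shrinks from the lower
    to the upper tail; qualitative emulation, not a reproduction claim.
    """
    def intercept(u):
        u = np.asarray(u, dtype=float)
        return 1.0 - 0.34 * (1.0 - u) ** 3.5

    return QuantileCoefficientFunction(
        intercept=intercept,
        effects={
            # age curves are constant in tau: any tau-slope scaled by an
            # extreme centered age would break latent monotonicity
            "race_NHB": shrinking_race_effect(-0.06, 0.02, 0.95),
            "race_Other": shrinking_race_effect(-0.05, 0.02, 0.40),
            "age_c": lambda u: np.full_like(np.asarray(u, dtype=float), 0.0012),
            "age_c2": lambda u: np.full_like(np.asarray(u, dtype=float), -5e-5),
        },
    )
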