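"""Empirical method comparison by resampling with replacement.

Repeatedly draws cohorts of ``n_per_replicate`` patients with replacement
from a source cohort (the resampling unit is the patient, so repeated
measures travel with their patient and the mixed model's clustering
survives), refits every requested method per replicate, and aggregates
the replicate estimates into means, SDs-as-SEs and exact empirical
2.5/97.5 percentiles.  Each replicate's random stream is derived from
(master seed, replicate index), so results do not depend on execution
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .pipeline import PERCENT_SCALE_NOTE, DisparityAnalysis, ModelSpec


@dataclass
class ResampleConfig:
    """Resampling-study settings.

    The full-scale design of the emulated study is 5,000 patients per
    replicate and 10,000 replications; the desk-scale default (200
    replications of 2,000 patients) preserves the design at tractable
    cost.
    """

    n_per_replicate: int = 2_000
    replications: int = 200
    seed: int = 0
    methods: tuple = ("qreg", "ols", "lmm")
    adjusted: bool = True
    max_failure_fraction: float = 0.10
    keep_replicates: bool = True

    def __post_init__(self):
        if self.replications < 2:
            raise ValueError("replications must be >= 2")
        if self.n_per_replicate < 3:
            raise ValueError("n_per_replicate too small")


def exact_percentile(values, prob):
    """Exact empirical percentile: smallest value whose ECDF >= prob."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    k = max(int(np.ceil(n * prob)), 1) - 1
    return float(v[min(k, n - 1)])


def summarize_percentiles(estimates: pd.DataFrame, probs=(0.025, 0.975)) -> pd.DataFrame:
    """Exact-percentile interval table from replicate estimates.

    ``estimates`` is long-format with columns (method, tau, term,
    estimate, replicate).  Empty cells are reported as missing, never
    fabricated.
    """
    rows = []
    for (method, tau, term), grp in estimates.groupby(
        ["method", "tau", "term"], dropna=False, sort=True
    ):
        v = grp["estimate"].to_numpy(dtype=float)
        if v.size < 2:
            rows.append((method, tau, term, *[np.nan] * len(probs)))
            continue
        rows.append((method, tau, term, *[exact_percentile(v, p) for p in probs]))
    cols = ["method", "tau", "term"] + [f"p{100 * p:g}" for p in probs]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class BootstrapSummary:
    """Aggregated resampling study (per method / level / term: mean
    estimate, SD-as-SE, exact 2.5 and 97.5 percentiles, failure count)."""

    table: pd.DataFrame
    config: ResampleConfig
    n_failures: int
    replicates: pd.DataFrame | None = field(default=None, repr=False)

    def to_csv(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {PERCENT_SCALE_NOTE}\n")
            self.table.to_csv(fh, index=False)

    def summary(self):
        return (
            f"Resampling study: {self.config.replications} replications of "
            f"n = {self.config.n_per_replicate} patients "
            f"({self.n_failures} failed fits); {PERCENT_SCALE_NOTE}\n"
            + self.table.to_string(index=False)
        )


def run_study(
    cohort: pd.DataFrame, spec: ModelSpec, config: ResampleConfig
) -> BootstrapSummary:
    """Patient-level resample / refit / aggregate loop.

    Replicates whose fits raise are recorded and excluded from
    aggregation; more than ``max_failure_fraction`` failures aborts with
    diagnostics.  Deterministic given ``config.seed``.
    """
    if len(cohort) < 1:
        raise ValueError("empty cohort")
    patients = cohort["patient_id"].unique()
    one_row_per_patient = not cohort["patient_id"].duplicated().any()
    if one_row_per_patient:
        pos = {pid: i for i, pid in enumerate(cohort["patient_id"])}
        by_patient = None
    else:
        by_patient = {pid: grp for pid, grp in cohort.groupby("patient_id", sort=False)}
    # quantile levels frozen from the source cohort so every replicate
    # fits the same levels
    taus = spec.quantile_levels(cohort[spec.outcome].to_numpy(dtype=float))
    frozen = ModelSpec(
        **{
            **{f: getattr(spec, f) for f in spec.__dataclass_fields__},
            "cutoffs": None,
            "taus": tuple(taus),
        }
    )
    records = []
    failures = []
    for rep in range(config.replications):
        rng = default_rng([config.seed, rep])
        chosen = rng.choice(patients, size=config.n_per_replicate, replace=True)
        if one_row_per_patient:
            sample = cohort.iloc[[pos[pid] for pid in chosen]].reset_index(drop=True)
            sample = sample.assign(patient_id=np.arange(config.n_per_replicate))
        else:
            sample = pd.concat(
                [by_patient[pid] for pid in chosen], ignore_index=True
            )
            # resampled duplicates must be distinct subjects for the LMM
            sample = sample.assign(
                patient_id=np.repeat(
                    np.arange(config.n_per_replicate),
                    [len(by_patient[pid]) for pid in chosen],
                )
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = DisparityAnalysis(sample, frozen).fit_all(
                    methods=config.methods, adjusted=config.adjusted, n_boot=0
                )
        except Exception as exc:  # noqa: BLE001 - failures are data, not bugs
            failures.append((rep, repr(exc)))
            continue
        t = comp.table[["term", "method", "tau", "estimate"]].copy()
        t["replicate"] = rep
        records.append(t)
    if len(failures) > config.max_failure_fraction * config.replications:
        raise RuntimeError(
            f"{len(failures)}/{config.replications} replicate fits failed; "
            f"first failures: {failures[:5]}"
        )
    if failures:
        warnings.warn(f"{len(failures)} replicate fits failed and were excluded")
    est = pd.concat(records, ignore_index=True)
    rows = []
    for (method, tau, term), grp in est.groupby(
        ["method", "tau", "term"], dropna=False, sort=True
    ):
        v = grp["estimate"].to_numpy(dtype=float)
        rows.append(
            (
                method,
                tau,
                term,
                float(v.mean()),
                float(v.std(ddof=1)),
                exact_percentile(v, 0.025),
                exact_percentile(v, 0.975),
                config.replications - v.size,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["method", "tau", "term", "mean", "se", "p2.5", "p97.5", "n_fail"],
    )
    return BootstrapSummary(
        table=table,
        config=config,
        n_failures=len(failures),
        replicates=est if config.keep_replicates else None,
    )
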