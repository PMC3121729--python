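"""Medication possession ratio (MPR) from pharmacy refill records.

MPR is the ratio of days of medication supplied to eligible days over the
follow-up, computed in consecutive 90-day refill windows anchored at a
patient's first fill in each drug class.  Windows run until the class
becomes inactive (last fill plus its days supplied); a partial final
window contributes its actual calendar days to the denominator.  Supplied
days are credited entirely to the window containing the fill date, classes
are pooled into one eligible/supplied pair per patient, and a ratio above
1 is capped at 1 (cap applied to the final ratio, not per window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WINDOW_DAYS = 90
KNOWN_CLASSES = frozenset({"HS501", "HS502"})  # insulin, oral hypoglycemics

REFILL_COLUMNS = ["patient_id", "drug_class", "fill_date", "days_supplied"]


@dataclass(frozen=True)
class Window:
    """Half-open refill window [start, end); end may be truncated."""

    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def days(self) -> int:
        return int((self.end - self.start).days)


@dataclass
class MPRResult:
    """Per-patient possession summary.

    ``mpr = min(1, supplied_days / eligible_days)``; ``capped`` is True
    iff the raw ratio exceeded 1.  ``per_window_ratio`` holds the uncapped
    per-window ratios for diagnostics only.
    """

    patient_id: object
    eligible_days: int
    supplied_days: int
    mpr: float
    capped: bool
    n_windows: int
    per_window_ratio: list


def validate_refills(records: pd.DataFrame, allow_any_class: bool = False) -> pd.DataFrame:
    """Validate and normalize a refill table (dates parsed, supplies >= 1)."""
    missing = [c for c in REFILL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"refill table missing columns: {missing}")
    out = records.copy()
    out["fill_date"] = pd.to_datetime(out["fill_date"], format="ISO8601")
    out["days_supplied"] = out["days_supplied"].astype(int)
    if (out["days_supplied"] < 1).any():
        bad = out.loc[out["days_supplied"] < 1]
        raise ValueError(f"days_supplied must be >= 1; offending rows:\n{bad.head()}")
    if not allow_any_class:
        unknown = set(out["drug_class"].unique()) - KNOWN_CLASSES
        if unknown:
            raise ValueError(
                f"unknown drug classes {sorted(unknown)}; pass allow_any_class=True "
                "to accept them"
            )
    return out


def read_refill_records(path, allow_any_class: bool = False) -> pd.DataFrame:
    """Read a comma-delimited refill file with ISO-8601 dates."""
    return validate_refills(pd.read_csv(path), allow_any_class=allow_any_class)


def _aggregate_same_day(dates: np.ndarray, supplies: np.ndarray):
    """Sum supplies of same-day fills (so fill-splitting cannot shorten
    the inactivity date) and return sorted unique dates + totals."""
    df = pd.DataFrame({"d": dates, "s": supplies}).groupby("d", sort=True)["s"].sum()
    return df.index.to_numpy(), df.to_numpy()


def build_windows(dates, supplies, window_len: int = DEFAULT_WINDOW_DAYS) -> list[Window]:
    """Consecutive refill windows for one patient-class record set.

    Windows of ``window_len`` days are anchored at the first fill date and
    end at the inactivity date (the latest ``fill date + days supplied``
    over same-day-aggregated fills); the final window is truncated there.
    An empty record set yields an empty window list.
    """
    dates = pd.to_datetime(np.asarray(dates))
    supplies = np.asarray(supplies, dtype=int)
    if len(dates) == 0:
        return []
    d, s = _aggregate_same_day(dates, supplies)
    start = pd.Timestamp(d[0])
    inactive = max(pd.Timestamp(di) + pd.Timedelta(days=int(si)) for di, si in zip(d, s))
    windows = []
    w0 = start
    step = pd.Timedelta(days=window_len)
    while w0 < inactive:
        windows.append(Window(w0, min(w0 + step, inactive)))
        w0 = w0 + step
    return windows


def _class_tally(dates, supplies, window_len):
    """(eligible, supplied, per-window supplied/eligible pairs) for one class."""
    windows = build_windows(dates, supplies, window_len)
    if not windows:
        return 0, 0, []
    dates = pd.to_datetime(np.asarray(dates))
    supplies = np.asarray(supplies, dtype=int)
    start = windows[0].start
    idx = ((dates - start).days // window_len).astype(int)
    per = []
    for k, w in enumerate(windows):
        per.append((int(supplies[idx == k].sum()), w.days))
    eligible = sum(e for _, e in per)
    supplied = int(supplies.sum())
    return eligible, supplied, per


def compute_mpr(
    records: pd.DataFrame,
    window_len: int = DEFAULT_WINDOW_DAYS,
    per_class: bool = False,
    allow_any_class: bool = False,
) -> list[MPRResult]:
    """Average MPR per patient from a refill table.

    Classes are pooled at the patient level (eligible and supplied days
    summed across classes) unless ``per_class=True``, in which case one
    result per (patient, class) is returned with ``patient_id`` set to a
    ``(patient, class)`` tuple.  Patients with zero eligible days are
    excluded with a warning (MPR undefined).
    """
    records = validate_refills(records, allow_any_class=allow_any_class)
    results = []
    dropped = []
    for pid, grp in records.groupby("patient_id", sort=True):
        tallies = {}
        for cls, sub in grp.groupby("drug_class", sort=True):
            tallies[cls] = _class_tally(
                sub["fill_date"].to_numpy(), sub["days_supplied"].to_numpy(), window_len
            )
        units = (
            [((pid, cls), [t]) for cls, t in tallies.items()]
            if per_class
            else [(pid, list(tallies.values()))]
        )
        for key, parts in units:
            eligible = sum(e for e, _, _ in parts)
            supplied = sum(s for _, s, _ in parts)
            per_window = [
                (sup / day if day > 0 else np.nan)
                for _, _, per in parts
                for sup, day in per
            ]
            n_windows = sum(len(per) for _, _, per in parts)
            if eligible <= 0:
                dropped.append(key)
                continue
            raw = supplied / eligible
            results.append(
                MPRResult(
                    patient_id=key,
                    eligible_days=eligible,
                    supplied_days=supplied,
                    mpr=min(1.0, raw),
                    capped=supplied > eligible,
                    n_windows=n_windows,
                    per_window_ratio=per_window,
                )
            )
    if dropped:
        warnings.warn(
            f"{len(dropped)} patients with zero eligible days excluded "
            f"(MPR undefined): {dropped[:5]}"
        )
    return results


def mpr_table(results: list[MPRResult]) -> pd.DataFrame:
    """Tidy MPR table (one row per patient) for model input or output."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "eligible_days": [r.eligible_days for r in results],
            "supplied_days": [r.supplied_days for r in results],
            "mpr": [r.mpr for r in results],
            "capped": [r.capped for r in results],
            "n_windows": [r.n_windows for r in results],
        }
    )


def write_mpr_table(results: list[MPRResult], path) -> None:
    mpr_table(results).to_csv(path, index=False)
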