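"""MPR engine tests: windows, pooling, cap, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adherence_qreg import build_windows, compute_mpr, mpr_table
from adherence_qreg.mpr import validate_refills


def _records(rows):
    return pd.DataFrame(rows, columns=["patient_id", "drug_class", "fill_date", "days_supplied"])


class TestBuildWindows:
    def test_single_full_window(self):
        w = build_windows(["2001-01-01"], [90])
        assert len(w) == 1
        assert str(w[0].start.date()) == "2001-01-01"
        assert str(w[0].end.date()) == "2001-04-01"
        assert w[0].days == 90

    def test_contiguous_refills(self):
        w = build_windows(["2001-01-01", "2001-04-01"], [90, 90])
        assert len(w) == 2
        assert sum(x.days for x in w) == 180

    def test_partial_final_window_truncated_at_inactivity(self):
        # second fill supplies 45 days -> windows cover days 0-135
        w = build_windows(["2001-01-01", "2001-04-01"], [90, 45])
        assert len(w) == 2
        assert [x.days for x in w] == [90, 45]

    def test_empty_records(self):
        assert build_windows([], []) == []


class TestComputeMPR:
    def test_full_adherence(self):
        res = compute_mpr(_records([(1, "HS501", "2001-01-01", 90)]))
        assert res[0].mpr == 1.0
        assert res[0].capped is False
        assert res[0].eligible_days == 90

    def test_two_window_hand_computation(self):
        # two full 90-day windows with 90 and 45 days supplied: a later
        # 45-day fill inside window 2 keeps the class active to day 180
        rec = _records(
            [(1, "HS501", "2001-01-01", 90),
             (1, "HS501", "2001-04-01", 45),
             (1, "HS501", "2001-05-16", 45)]
        )
        # remove the third fill's supply contribution by comparing shapes
        res = compute_mpr(rec)[0]
        assert res.eligible_days == 180
        assert res.supplied_days == 180

    def test_pooled_ratio(self, refills_two_windows):
        res = compute_mpr(refills_two_windows)[0]
        assert res.supplied_days == 135
        assert res.eligible_days == 135

    def test_cap_rule_overlapping_fills(self):
        # 120 days supplied against one 90-day window -> capped at 1
        rec = _records(
            [(1, "HS501", "2001-01-01", 90), (1, "HS501", "2001-03-02", 30)]
        )
        res = compute_mpr(rec)[0]
        assert res.eligible_days == 90
        assert res.supplied_days == 120
        assert res.mpr == 1.0
        assert res.capped is True

    def test_half_adherence_two_windows(self):
        rec = _records(
            [(1, "HS501", "2001-01-01", 90),
             (1, "HS501", "2001-04-01", 45),
             (1, "HS501", "2001-09-27", 1)]  # keeps follow-up to day 270? no: day 269+1
        )
        res = compute_mpr(rec)[0]
        assert res.mpr == pytest.approx(res.supplied_days / res.eligible_days)

    def test_classes_pooled_by_default(self):
        rec = _records(
            [(1, "HS501", "2001-01-01", 90), (1, "HS502", "2001-01-01", 45)]
        )
        res = compute_mpr(rec)[0]
        assert res.eligible_days == 90 + 45
        assert res.mpr == 1.0
        per = compute_mpr(rec, per_class=True)
        assert {r.patient_id for r in per} == {(1, "HS501"), (1, "HS502")}

    def test_unknown_class_rejected_unless_allowed(self):
        rec = _records([(1, "XX999", "2001-01-01", 90)])
        with pytest.raises(ValueError, match="XX999"):
            compute_mpr(rec)
        assert compute_mpr(rec, allow_any_class=True)[0].mpr == 1.0

    def test_invalid_days_supplied(self):
        rec = _records([(1, "HS501", "2001-01-01", 0)])
        with pytest.raises(ValueError, match="days_supplied"):
            validate_refills(rec)

    def test_mpr_table_columns(self, refills_two_windows):
        tab = mpr_table(compute_mpr(refills_two_windows))
        assert list(tab.columns) == [
            "patient_id", "eligible_days", "supplied_days", "mpr", "capped", "n_windows",
        ]


@st.composite
def refill_history(draw):
    n = draw(st.integers(1, 6))
    rows = []
    for _ in range(n):
        day = draw(st.integers(0, 400))
        supply = draw(st.integers(1, 120))
        rows.append((1, "HS501", str(pd.Timestamp("2001-01-01") + pd.Timedelta(days=day)), supply))
    return _records(rows)


class TestInvariances:
    @given(rec=refill_history())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_bounds_and_order_invariance(self, rec):
        res = compute_mpr(rec)[0]
        assert 0.0 <= res.mpr <= 1.0
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = compute_mpr(shuffled)[0]
        assert res2.mpr == res.mpr
        assert res2.eligible_days == res.eligible_days

    @given(rec=refill_history(), frac=st.integers(1, 99))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_same_day_fill_splitting_invariance(self, rec, frac):
        res = compute_mpr(rec)[0]
        row = rec.iloc[0]
        if row["days_supplied"] < 2:
            return
        a = max(1, row["days_supplied"] * frac // 100)
        b = row["days_supplied"] - a
        if b < 1:
            return
        split = pd.concat(
            [rec.iloc[1:],
             _records([(1, "HS501", row["fill_date"], a), (1, "HS501", row["fill_date"], b)])],
            ignore_index=True,
        )
        res2 = compute_mpr(split)[0]
        assert res2.mpr == res.mpr
        assert res2.eligible_days == res.eligible_days

    def test_adding_fill_never_decreases_supplied(self, refills_two_windows):
        base = compute_mpr(refills_two_windows)[0]
        extra = pd.concat(
            [refills_two_windows, _records([(1, "HS501", "2001-02-01", 10)])],
            ignore_index=True,
        )
        assert compute_mpr(extra)[0].supplied_days >= base.supplied_days
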