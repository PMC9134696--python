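"""Cleaning, imputation, chronic flagging and quintile tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chesurvey.errors import ValidationError
from chesurvey.preprocess import (
    DISEASE_NAMES,
    WEEKS_PER_MONTH,
    assign_economic_quintile,
    clean_records,
    deflate_to_monthly,
    flag_chronic_household,
)

from conftest import minimal_raw_survey


def members_frame(rows):
    """rows: list of (household_id, is_householder, diseases_dict)."""
    data = []
    for hid, head, diseases in rows:
        row = {"household_id": hid, "member_index": 0, "is_householder": int(head), "age": 60}
        for d in DISEASE_NAMES:
            row[d] = int(diseases.get(d, 0))
        data.append(row)
    df = pd.DataFrame(data)
    df["member_index"] = df.groupby("household_id").cumcount()
    return df


class TestDeflate:
    def test_weekly_food_to_monthly(self):
        raw = minimal_raw_survey(pd.DataFrame({"household_id": ["A"], "food_weekly": [70.0]}))
        out = deflate_to_monthly(raw)
        assert out.households["food_month"].iloc[0] == pytest.approx(70.0 * (365.25 / 7) / 12)
        assert out.households["food_month"].iloc[0] == pytest.approx(304.375)

    def test_annual_oop_to_monthly(self):
        raw = minimal_raw_survey(pd.DataFrame({"household_id": ["A"], "oop_annual": [1200.0]}))
        assert deflate_to_monthly(raw).households["oop_month"].iloc[0] == pytest.approx(100.0)

    def test_cpi_factor_applied(self):
        raw = minimal_raw_survey(
            pd.DataFrame({"household_id": ["A"], "oop_annual": [1200.0], "interview_month": [6]})
        )
        out = deflate_to_monthly(raw, cpi_index={6: 1.25})
        assert out.households["oop_month"].iloc[0] == pytest.approx(80.0)

    def test_negative_money_rejected(self):
        raw = minimal_raw_survey(pd.DataFrame({"household_id": ["A"], "food_weekly": [-1.0]}))
        with pytest.raises(ValidationError, match="A"):
            deflate_to_monthly(raw)

    def test_missing_cpi_month_rejected(self):
        raw = minimal_raw_survey(pd.DataFrame({"household_id": ["A"], "interview_month": [2]}))
        with pytest.raises(ValidationError):
            deflate_to_monthly(raw, cpi_index={1: 1.0})


class TestCleanRecords:
    def build(self):
        hh = pd.DataFrame(
            {
                "household_id": ["A", "B", "C", "D"],
                "food_weekly": [70.0, 70.0, np.nan, 70.0],
                "oop_annual": [np.nan, 600.0, 0.0, np.nan],
                "oop_outpatient_annual": [40.0 * 12, 0.0, 0.0, np.nan],
                "oop_inpatient_annual": [60.0 * 12, 0.0, 0.0, np.nan],
                "hhsize_reported": [np.nan, 2.0, 1.0, 1.0],
            }
        )
        members = members_frame(
            [("A", 1, {}), ("A", 0, {}), ("A", 0, {}), ("B", 1, {}), ("C", 1, {}), ("D", 1, {})]
        )
        return minimal_raw_survey(hh, members)

    def test_supplement_and_delete_rules(self):
        records, log = clean_records(deflate_to_monthly(self.build()))
        # A: OOP supplemented from parts (monthly 40 + 60)
        a = records.set_index("household_id").loc["A"]
        assert a["oop_month"] == pytest.approx(100.0)
        # A: size supplemented from the 3 member rows under the same family code
        assert a["hhsize"] == 3
        # C dropped (food missing, unsupplementable); D dropped (OOP and parts missing)
        assert set(records["household_id"]) == {"A", "B"}
        rules = {r: (rem, left) for r, rem, left in log.rows}
        assert rules["drop_missing_food"] == (1, 3)
        assert rules["drop_unsupplementable_oop"] == (1, 2)
        assert log.reconciles()
        assert log.final == 2

    def test_imputation_never_changes_observed_values(self):
        raw = deflate_to_monthly(self.build())
        before = raw.households.set_index("household_id")
        records, _ = clean_records(raw)
        b = records.set_index("household_id").loc["B"]
        assert b["oop_month"] == pytest.approx(before.loc["B", "oop_annual"] / 12)
        assert b["hhsize"] == 2

    def test_no_member_rows_is_logged_not_raised(self):
        hh = pd.DataFrame(
            {
                "household_id": ["A", "B"],
                "food_weekly": [70.0, 70.0],
                "hhsize_reported": [1.0, np.nan],
            }
        )
        members = members_frame([("A", 1, {})])
        records, log = clean_records(deflate_to_monthly(minimal_raw_survey(hh, members)))
        assert list(records["household_id"]) == ["A"]
        assert dict((r, rem) for r, rem, _ in log.rows)["drop_unsupplementable_size"] == 1

    def test_requires_deflation_first(self):
        with pytest.raises(ValidationError, match="deflate"):
            clean_records(self.build())


class TestChronicFlag:
    def test_all_healthy(self):
        members = members_frame([("A", 1, {}), ("A", 0, {})])
        out = flag_chronic_household(members)
        assert not out.loc["A", "chronic_household"]
        assert out.loc["A", "disease_count_class"] == "none"

    def test_any_member_flags_household(self):
        # a non-householder member with diabetes makes the household chronic,
        # but the householder-level indicators stay No
        members = members_frame([("A", 1, {}), ("A", 0, {"diabetes": 1})])
        out = flag_chronic_household(members)
        assert out.loc["A", "chronic_household"]
        assert out.loc["A", "diabetes"] == "No"
        assert out.loc["A", "disease_count_class"] == "none"

    def test_householder_counts_set_class(self):
        members = members_frame(
            [("A", 1, {"diabetes": 1}), ("B", 1, {"stroke": 1, "diabetes": 1})]
        )
        out = flag_chronic_household(members)
        assert out.loc["A", "disease_count_class"] == "1"
        assert out.loc["A", "diabetes"] == "Yes"
        assert out.loc["B", "disease_count_class"] == ">1"

    def test_incomplete_answers_rejected(self):
        members = members_frame([("A", 1, {})])
        members.loc[0, "asthma"] = np.nan
        with pytest.raises(ValidationError):
            flag_chronic_household(members)


class TestQuintiles:
    def frame(self, per_capita, ids=None):
        n = len(per_capita)
        ids = ids if ids is not None else [f"H{i:03d}" for i in range(n)]
        return pd.DataFrame(
            {
                "household_id": ids,
                "exp_month": np.asarray(per_capita, dtype=float),
                "hhsize": np.ones(n, dtype=int),
            }
        )

    def test_distinct_values_split_evenly(self):
        out = assign_economic_quintile(self.frame(np.arange(10.0) + 1))
        levels = out.sort_values("exp_month")["economic_level"].tolist()
        assert levels == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_ties_stable_order(self):
        out = assign_economic_quintile(self.frame(np.full(10, 7.0)))
        assert out["economic_level"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_remainder_allocation(self):
        out = assign_economic_quintile(self.frame(np.arange(12.0)))
        sizes = out["economic_level"].value_counts().sort_index().tolist()
        assert sizes == [3, 3, 2, 2, 2]

    def test_scale_and_order_invariance(self):
        rng = np.random.default_rng(3)
        base = self.frame(rng.lognormal(7, 1, 100))
        ref = assign_economic_quintile(base).set_index("household_id")["economic_level"]
        scaled = base.copy()
        scaled["exp_month"] *= 1e4
        out_scaled = assign_economic_quintile(scaled).set_index("household_id")["economic_level"]
        shuffled = base.sample(frac=1.0, random_state=0)
        out_shuffled = assign_economic_quintile(shuffled).set_index("household_id")["economic_level"]
        pd.testing.assert_series_equal(ref, out_scaled)
        pd.testing.assert_series_equal(ref.sort_index(), out_shuffled.sort_index())

    def test_too_few_households_rejected(self):
        with pytest.raises(ValidationError):
            assign_economic_quintile(self.frame([1.0, 2.0]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 50), min_size=5, max_size=40))
    def test_group_sizes_differ_by_at_most_one(self, values):
        out = assign_economic_quintile(self.frame([float(v) for v in values]))
        sizes = out["economic_level"].value_counts().reindex(range(1, 6), fill_value=0)
        assert sizes.sum() == len(values)
        assert sizes.max() - sizes.min() <= 1
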