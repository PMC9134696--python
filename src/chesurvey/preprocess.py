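"""Survey cleaning: deflation to monthly terms, deterministic imputation,
exclusion logging, chronic-disease flagging, and expenditure quintiles.

The cleaning rules are deterministic supplements, applied in a fixed order:

1. a missing annual OOP total is supplemented by the sum of its outpatient and
   inpatient parts when both are present;
2. a missing household size is supplemented by the number of member rows under
   the same family code;
3. households whose food expenditure is still missing are deleted (it cannot
   be supplemented), as are households whose OOP or size could not be
   supplemented or whose consumption expenditure is missing/non-positive.

Every removal is logged in an :class:`ExclusionLog` whose counts reconcile
(initial - sum removed = final).  Imputation never changes a non-missing
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: weekly -> monthly conversion factor: (365.25 / 7) weeks per year / 12 months
WEEKS_PER_MONTH = (365.25 / 7.0) / 12.0
MONTHS_PER_YEAR = 12.0

#: the 14 chronic-condition indicators in the member-level table
DISEASE_NAMES = (
    "hypertension",
    "dyslipidaemia",
    "diabetes",
    "malignant_tumour",
    "chronic_lung_disease",
    "liver_disease",
    "heart_disease",
    "stroke",
    "kidney_disease",
    "stomach_disease",
    "emotional_problems",
    "memory_disease",
    "arthritis",
    "asthma",
)

#: the five focal conditions carried as household-level indicators
FOCAL_DISEASES = (
    "heart_disease",
    "stroke",
    "malignant_tumour",
    "chronic_lung_disease",
    "diabetes",
)


@dataclass
class RawSurvey:
    """Pre-cleaning survey: a household table, a member table, and the
    missingness configuration used to generate them (empty for real data)."""

    households: pd.DataFrame
    members: pd.DataFrame
    missing_config: dict = field(default_factory=dict)
    #: generator ground truth (per-household CHE probability etc.); None for real data
    truth: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.households)

    def copy(self) -> "RawSurvey":
        return RawSurvey(
            self.households.copy(),
            self.members.copy(),
            dict(self.missing_config),
            None if self.truth is None else self.truth.copy(),
        )


@dataclass
class ExclusionLog:
    """Ordered record of cleaning rules: (rule, removed, remaining)."""

    initial: int
    rows: list = field(default_factory=list)

    def add(self, rule: str, removed: int, remaining: int) -> None:
        if self.rows and remaining > self.rows[-1][2]:
            raise ValidationError("exclusion log counts must be non-increasing")
        self.rows.append((rule, int(removed), int(remaining)))

    @property
    def final(self) -> int:
        return self.rows[-1][2] if self.rows else self.initial

    def reconciles(self) -> bool:
        return self.initial - sum(r[1] for r in self.rows) == self.final

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "removed", "remaining"])


# ---------------------------------------------------------------------------
# Deflation
# ---------------------------------------------------------------------------


def deflate_to_monthly(raw: RawSurvey, cpi_index: dict | None = None) -> RawSurvey:
    """Convert reported monetary fields to deflated monthly terms.

    Weekly food spending is multiplied by (365.25/7)/12; annual OOP (total and
    parts) divided by 12; each household's monetary fields are then divided by
    the CPI factor of its interview month (``cpi_index``: month -> factor;
    ``None`` means the identity, leaving nominal values).  Adds food_month,
    oop_month, oop_outpatient_month, oop_inpatient_month columns and deflates
    exp_month in place.
    """
    out = raw.copy()
    hh = out.households
    money_in = ["food_weekly", "exp_month", "oop_annual", "oop_outpatient_annual", "oop_inpatient_annual"]
    for col in money_in:
        if col in hh.columns and (hh[col].dropna() < 0).any():
            bad = hh.loc[hh[col] < 0, "household_id"].iloc[0]
            raise ValidationError(f"household {bad!r}: negative value in {col!r}")

    if cpi_index is None:
        factor = np.ones(len(hh))
    else:
        months = hh["interview_month"]
        missing = ~months.isin(cpi_index.keys())
        if missing.any():
            bad = hh.loc[missing, "household_id"].iloc[0]
            raise ValidationError(f"household {bad!r}: no CPI factor for its interview month")
        factor = months.map(cpi_index).to_numpy(dtype=float)

    hh["food_month"] = hh["food_weekly"] * WEEKS_PER_MONTH / factor
    hh["oop_month"] = hh["oop_annual"] / MONTHS_PER_YEAR / factor
    hh["oop_outpatient_month"] = hh["oop_outpatient_annual"] / MONTHS_PER_YEAR / factor
    hh["oop_inpatient_month"] = hh["oop_inpatient_annual"] / MONTHS_PER_YEAR / factor
    hh["exp_month"] = hh["exp_month"] / factor
    return out


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean_records(raw: RawSurvey):
    """Apply the supplement-then-delete rules; returns ``(records, log)``.

    ``records`` is a household DataFrame with hhsize filled, oop_month
    supplemented, and all unsupplementable households removed; covariate
    columns are carried through unchanged.  Requires :func:`deflate_to_monthly`
    to have run (food_month/oop_month columns present).
    """
    hh = raw.households.copy()
    if "food_month" not in hh.columns:
        raise ValidationError("survey not deflated: run deflate_to_monthly first")
    log = ExclusionLog(initial=len(hh))

    # 1. supplement missing OOP total from outpatient + inpatient parts
    parts_ok = hh["oop_outpatient_month"].notna() & hh["oop_inpatient_month"].notna()
    fill = hh["oop_month"].isna() & parts_ok
    hh.loc[fill, "oop_month"] = (
        hh.loc[fill, "oop_outpatient_month"] + hh.loc[fill, "oop_inpatient_month"]
    )
    log.add("supplement_oop_from_parts", 0, len(hh))

    # 2. supplement missing household size from member rows with the same family code
    member_counts = raw.members.groupby("household_id").size()
    fill = hh["hhsize_reported"].isna()
    hh.loc[fill, "hhsize_reported"] = hh.loc[fill, "household_id"].map(member_counts)
    log.add("supplement_size_from_members", 0, len(hh))

    # 3. deletions, in the order the rules were stated
    for rule, rule_fn in (
        ("drop_missing_food", lambda d: d["food_month"].isna()),
        ("drop_unsupplementable_oop", lambda d: d["oop_month"].isna()),
        ("drop_unsupplementable_size", lambda d: d["hhsize_reported"].isna()),
        ("drop_missing_or_nonpositive_exp", lambda d: d["exp_month"].isna() | (d["exp_month"] <= 0)),
    ):
        mask = rule_fn(hh)
        removed = int(mask.sum())
        hh = hh.loc[~mask]
        log.add(rule, removed, len(hh))

    # food above total consumption is kept but noted (the capacity-to-pay
    # branch rule absorbs it downstream)
    n_flag = int((hh["food_month"] > hh["exp_month"]).sum())
    log.add("flag_food_exceeds_exp", 0, len(hh))
    log.rows[-1] = (f"flag_food_exceeds_exp[n={n_flag}]", 0, len(hh))

    hh = hh.copy()
    hh["hhsize"] = hh["hhsize_reported"].astype(int)
    hh["size_class"] = np.select(
        [hh["hhsize"] == 1, hh["hhsize"] == 2], ["1", "2"], default="3+"
    )
    hh["age_group"] = np.where(hh["age"] < 65, "<65", "65+")
    if "weight" not in hh.columns:
        hh["weight"] = 1.0
    if not log.reconciles():
        raise ValidationError("exclusion log does not reconcile")
    return hh.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Chronic-disease flags
# ---------------------------------------------------------------------------


def flag_chronic_household(members: pd.DataFrame) -> pd.DataFrame:
    """Household-level chronic-disease summary from the member table.

    A household is chronic iff any member answers yes to at least one of the
    14 conditions.  The five focal disease indicators and the 1-type vs
    more-than-one-type class come from the householder's own answers.
    Returns a DataFrame indexed by household_id with columns
    chronic_household, the five focal indicators ("Yes"/"No"), and
    disease_count_class ("none", "1", ">1").
    """
    missing = [c for c in DISEASE_NAMES if c not in members.columns]
    if missing:
        raise ValidationError(f"member table lacks disease answers: {missing}")
    if members[list(DISEASE_NAMES)].isna().any().any():
        bad = members.loc[
            members[list(DISEASE_NAMES)].isna().any(axis=1), "household_id"
        ].iloc[0]
        raise ValidationError(
            f"household {bad!r}: a member has fewer than 14 disease answers"
        )
    answers = members[list(DISEASE_NAMES)].astype(bool)
    any_disease = answers.any(axis=1)
    chronic = any_disease.groupby(members["household_id"]).any()

    heads = members.loc[members["is_householder"].astype(bool)]
    head_answers = heads.set_index("household_id")[list(DISEASE_NAMES)].astype(bool)
    n_cond = head_answers.sum(axis=1)
    out = pd.DataFrame(index=chronic.index)
    out["chronic_household"] = chronic
    for disease in FOCAL_DISEASES:
        flag = head_answers[disease].reindex(out.index).fillna(False)
        out[disease] = np.where(flag, "Yes", "No")
    counts = n_cond.reindex(out.index).fillna(0)
    out["disease_count_class"] = np.select(
        [counts == 0, counts == 1], ["none", "1"], default=">1"
    )
    out.index.name = "household_id"
    return out


# ---------------------------------------------------------------------------
# Economic quintiles
# ---------------------------------------------------------------------------


def assign_economic_quintile(records: pd.DataFrame) -> pd.DataFrame:
    """Rank households by per-capita consumption expenditure and split into
    five near-equal groups (level 1 = poorest ... 5 = wealthiest).

    Ties are broken by stable household_id order, so the assignment is
    invariant to input row order and to currency rescaling.  Group sizes
    differ by at most one; the poorer groups absorb the remainder.
    """
    n = len(records)
    if n < 5:
        raise ValidationError("need at least 5 households to form quintiles")
    out = records.copy()
    per_capita = out["exp_month"].to_numpy(dtype=float) / out["hhsize"].to_numpy(dtype=float)
    order = pd.DataFrame(
        {"pc": per_capita, "hid": out["household_id"].to_numpy()}
    ).sort_values(["pc", "hid"], kind="mergesort")
    base, extra = divmod(n, 5)
    sizes = [base + (1 if g < extra else 0) for g in range(5)]
    levels = np.repeat(np.arange(1, 6), sizes)
    assignment = pd.Series(levels, index=order.index)
    out["economic_level"] = assignment.sort_index().to_numpy()
    return out


def read_survey(household_csv, member_csv) -> RawSurvey:
    """Load the two-CSV survey layout (see the column dictionary in README)."""
    households = pd.read_csv(household_csv)
    members = pd.read_csv(member_csv)
    if "household_id" not in households.columns or "household_id" not in members.columns:
        raise ValidationError("both CSVs need a household_id column")
    return RawSurvey(households=households, members=members)
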