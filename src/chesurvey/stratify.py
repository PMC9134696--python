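"""Stratified CHE incidence tables and chi-square group comparisons.

Produces the descriptive analysis surface of a CHE study: per-stratum
frequency, CHE count and incidence (percent) for each covariate, a Pearson
chi-square comparison across strata, per-quintile monetary/incidence
summaries for the chronic-disease subsample versus the full sample, and the
disease-by-utilisation tables (two comparison families: condition contrasts
within each disease group, and disease-vs-no-disease contrasts within each
condition level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .preprocess import FOCAL_DISEASES


def chi_square_test(contingency, yates: bool = False):
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default (``yates=True`` enables it for 2x2).
    Returns ``(statistic, df, p)``.  A zero row or column margin raises,
    naming the offending margin.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValidationError("contingency counts must be non-negative")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(row_sums == 0):
        raise ValidationError(f"zero row margin at row {int(np.argmax(row_sums == 0))}")
    if np.any(col_sums == 0):
        raise ValidationError(f"zero column margin at column {int(np.argmax(col_sums == 0))}")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class IncidenceTable:
    """Stratified CHE incidence with its chi-square comparison.

    ``table`` has one row per stratum: label, n (weighted frequency),
    che (weighted CHE count), incidence (percent).  ``scope`` distinguishes
    the comparison family for the disease tables.
    """

    stratifier: str
    table: pd.DataFrame = field(repr=False)
    chi_square: float | None
    df: int | None
    p_value: float | None
    scope: str = "strata"
    dropped_strata: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["incidence"] = out["incidence"].round(2)
        out.insert(0, "stratifier", self.stratifier)
        return out


def incidence_table(
    records: pd.DataFrame,
    stratifier: str,
    cata_column: str = "cata",
    weight_column: str = "weight",
    order=None,
    scope: str = "strata",
    yates: bool = False,
) -> IncidenceTable:
    """Per-stratum weighted N, CHE count and incidence, plus the chi-square
    comparison over the strata x (CHE, no CHE) contingency table.

    Empty strata (from a supplied ``order``) are dropped with a note.  With a
    single non-empty stratum the chi-square fields are None.
    """
    if stratifier not in records.columns:
        raise ValidationError(f"records lack stratifier column {stratifier!r}")
    w = (
        records[weight_column].to_numpy(dtype=float)
        if weight_column in records.columns
        else np.ones(len(records))
    )
    cata = records[cata_column].to_numpy(dtype=float)
    labels = records[stratifier]
    if order is None:
        order = sorted(labels.unique(), key=str)
    rows, dropped, counts = [], [], []
    for label in order:
        mask = (labels == label).to_numpy()
        n_w = float(w[mask].sum())
        if n_w == 0:
            dropped.append(label)
            continue
        che_w = float((w[mask] * cata[mask]).sum())
        rows.append(
            {"label": label, "n": n_w, "che": che_w, "incidence": 100.0 * che_w / n_w}
        )
        counts.append([che_w, n_w - che_w])
    if not rows:
        raise ValidationError(f"no non-empty strata for {stratifier!r}")
    table = pd.DataFrame(rows)
    if len(rows) >= 2 and all(sum(c) > 0 for c in counts) and sum(c[0] for c in counts) > 0 and sum(
        c[1] for c in counts
    ) > 0:
        statistic, dof, p = chi_square_test(np.array(counts), yates=yates)
    else:
        statistic = dof = p = None
    return IncidenceTable(
        stratifier=stratifier,
        table=table,
        chi_square=statistic,
        df=dof,
        p_value=p,
        scope=scope,
        dropped_strata=dropped,
    )


def quintile_summary(records: pd.DataFrame, chronic_column: str = "chronic_household") -> pd.DataFrame:
    """Per-quintile mean monthly consumption expenditure and CHE incidence,
    for the chronic-disease subsample and the full sample.

    ``records`` must carry economic_level, exp_month, cata, weight and the
    chronic flag.  Cells with no households are left missing (NaN).
    """
    populations = {
        "full_sample": records,
        "chronic_subsample": records.loc[records[chronic_column].astype(bool)],
    }
    rows = []
    for level in (1, 2, 3, 4, 5):
        row = {"economic_level": level}
        for name, pop in populations.items():
            sub = pop.loc[pop["economic_level"] == level]
            w = sub["weight"].to_numpy(dtype=float) if "weight" in sub.columns else np.ones(len(sub))
            if len(sub) == 0 or w.sum() == 0:
                row[f"mean_exp_{name}"] = np.nan
                row[f"incidence_{name}"] = np.nan
                row[f"n_{name}"] = 0.0
                continue
            row[f"mean_exp_{name}"] = float(np.sum(w * sub["exp_month"].to_numpy()) / w.sum())
            row[f"incidence_{name}"] = float(100.0 * np.sum(w * sub["cata"].to_numpy()) / w.sum())
            row[f"n_{name}"] = float(w.sum())
        rows.append(row)
    return pd.DataFrame(rows)


#: the utilisation/demand conditions the disease tables are stratified by
CONDITION_COLUMNS = (
    "self_rated_health",
    "member_65",
    "disabled",
    "disease_count_class",
    "outpatient",
    "inpatient",
)


def disease_condition_tables(
    records: pd.DataFrame,
    conditions=CONDITION_COLUMNS,
    diseases=FOCAL_DISEASES,
    chronic_column: str = "chronic_household",
):
    """The two comparison families of the disease-by-condition analysis.

    Family 1 (scope ``within_disease``): for each disease group (all chronic
    households, then households whose householder has each focal disease),
    compare CHE incidence across the levels of each condition.

    Family 2 (scope ``disease_vs_none``): within each condition level, compare
    chronic households against households without any chronic disease.

    Returns a list of :class:`IncidenceTable`.
    """
    chronic = records[chronic_column].astype(bool)
    groups = {"families_with_disease": records.loc[chronic]}
    for disease in diseases:
        groups[disease] = records.loc[chronic & (records[disease] == "Yes")]
    tables = []
    for cond in conditions:
        if cond not in records.columns:
            continue
        for group_name, group in groups.items():
            if len(group) == 0:
                continue
            try:
                t = incidence_table(group, cond, scope="within_disease")
            except ValidationError:
                continue
            t.stratifier = f"{group_name}:{cond}"
            tables.append(t)
        # family 2: disease vs none at each condition level
        none = records.loc[~chronic]
        for level in sorted(records[cond].unique(), key=str):
            sub = records.loc[records[cond] == level].copy()
            if len(sub) == 0:
                continue
            sub["family_type"] = np.where(
                sub[chronic_column].astype(bool), "with_disease", "without_disease"
            )
            if sub["family_type"].nunique() < 2:
                continue
            t = incidence_table(sub, "family_type", scope="disease_vs_none")
            t.stratifier = f"{cond}={level}:disease_vs_none"
            tables.append(t)
        del none
    return tables
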