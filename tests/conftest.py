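import numpy as np
import pandas as pd
import pytest

from chesurvey import SyntheticConfig, generate_survey
from chesurvey.preprocess import (
    DISEASE_NAMES,
    RawSurvey,
    assign_economic_quintile,
    clean_records,
    deflate_to_monthly,
    flag_chronic_household,
)
from chesurvey import che


def random_toy_households(n, seed):
    """Monetary fields with broad, uncorrelated variation (no CHE mechanism)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "household_id": [f"T{i:05d}" for i in range(n)],
            "food_month": rng.lognormal(6.0, 0.8, n),
            "exp_month": rng.lognormal(7.5, 0.9, n),
            "oop_month": np.where(rng.uniform(size=n) < 0.3, 0.0, rng.lognormal(5.0, 1.6, n)),
            "hhsize": rng.integers(1, 7, n),
            "weight": np.ones(n),
        }
    )


@pytest.fixture(scope="session")
def toy_records():
    return random_toy_households(1000, seed=20240)


@pytest.fixture(scope="session")
def small_survey():
    cfg = SyntheticConfig(n_households=1500, seed=11)
    return cfg, generate_survey(cfg)


@pytest.fixture(scope="session")
def analysed_small(small_survey):
    """Cleaned, flagged, quintiled records joined with CHE results."""
    _, raw = small_survey
    deflated = deflate_to_monthly(raw)
    records, log = clean_records(deflated)
    chronic = flag_chronic_household(deflated.members)
    records = records.merge(chronic, on="household_id", how="left")
    records["chronic_household"] = records["chronic_household"].fillna(False).astype(bool)
    records = assign_economic_quintile(records)
    result = che.run_che(records)
    merged = records.merge(result.results[["household_id", "oopctp", "cata"]], on="household_id")
    return merged, result, log


def minimal_raw_survey(households: pd.DataFrame, members: pd.DataFrame | None = None) -> RawSurvey:
    """Build a RawSurvey from a partial household frame, filling the columns
    the cleaning stage expects."""
    hh = households.copy()
    defaults = {
        "interview_month": 6,
        "weight": 1.0,
        "food_weekly": np.nan,
        "exp_month": 1000.0,
        "oop_annual": 0.0,
        "oop_outpatient_annual": 0.0,
        "oop_inpatient_annual": 0.0,
        "hhsize_reported": 1.0,
        "age": 60.0,
    }
    for col, value in defaults.items():
        if col not in hh.columns:
            hh[col] = value
    if members is None:
        members = pd.DataFrame(
            {
                "household_id": hh["household_id"],
                "member_index": 0,
                "is_householder": 1,
                "age": hh["age"],
                **{d: 0 for d in DISEASE_NAMES},
            }
        )
    return RawSurvey(households=hh, members=members)
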