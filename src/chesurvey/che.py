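"""WHO catastrophic health expenditure (CHE) chain.

Implements the capacity-to-pay methodology on a cleaned household survey:

1. food share          foodexp_h = food_h / exp_h
2. equivalised size    eqsize_h  = hhsize_h ** beta          (beta = 0.56)
3. equivalised food    eqfood_h  = food_h / eqsize_h
4. poverty line        pl        = weighted mean of eqfood_h over households whose
                                   food share lies strictly inside the 45th-55th
                                   percentile band of the food-share ranking
5. subsistence         se_h      = pl * eqsize_h
6. capacity to pay     ctp_h     = exp_h - se_h   if se_h <= food_h
                                   exp_h - food_h if se_h >= food_h
7. OOP burden          oopctp_h  = oop_h / ctp_h
8. CHE flag            cata_h    = 1 iff oopctp_h >= threshold   (threshold = 0.40)

All monetary inputs must already be on a common monthly, deflated scale
(see :mod:`chesurvey.preprocess`).  Only the poverty line couples households;
every other step is per-household.  The chain is equivariant under a common
currency rescaling: pl, se_h and ctp_h scale with the money, foodexp_h,
oopctp_h and every cata_h are unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BandError, DegenerateHouseholdError, ValidationError

#: default equivalence-scale exponent (estimated from household surveys in 59 countries)
DEFAULT_BETA = 0.56
#: default CHE threshold on the OOP share of capacity to pay
DEFAULT_THRESHOLD = 0.40
#: default percentile band used for the food-share poverty line
DEFAULT_BAND = (45.0, 55.0)


def food_share(food_h, exp_h):
    """Food share of household consumption, ``food_h / exp_h``.

    Not clamped: shares above 1 (food reported above total consumption) are
    passed through and handled by the capacity-to-pay branch rule.
    """
    food_h = np.asarray(food_h, dtype=float)
    exp_h = np.asarray(exp_h, dtype=float)
    if np.any(exp_h <= 0):
        raise DegenerateHouseholdError(
            "household consumption expenditure must be positive to form a food share"
        )
    return food_h / exp_h


def equivalized_size(hhsize_h, beta: float = DEFAULT_BETA):
    """Equivalence-scale household size ``hhsize_h ** beta``."""
    hhsize_h = np.asarray(hhsize_h, dtype=float)
    if beta <= 0:
        raise ValidationError("equivalence exponent beta must be positive")
    if np.any(hhsize_h < 1):
        raise ValidationError("household size must be >= 1")
    return hhsize_h**beta


def poverty_line(rank_values, eqfood, weights=None, band=DEFAULT_BAND):
    """Survey-level poverty line: weighted mean equivalised food expenditure
    over households whose ranking value lies strictly inside the percentile band.

    Parameters
    ----------
    rank_values
        The variable defining the band, normally the food share (WHO
        convention); an alternative key (e.g. total expenditure) may be passed.
    eqfood
        Equivalised food expenditure per household.
    weights
        Optional non-negative household weights; default 1.
    band
        (lower, upper) percentiles, default (45, 55).  Percentile values are
        computed with linear interpolation between order statistics.  Selection
        uses strict inequalities; if the open band is empty (tiny surveys, heavy
        ties) the closed band ``[p_lo, p_hi]`` is used as a fallback.
    """
    rank_values = np.asarray(rank_values, dtype=float)
    eqfood = np.asarray(eqfood, dtype=float)
    n = rank_values.size
    if n == 0:
        raise BandError("cannot compute a poverty line for an empty survey")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    lo, hi = band
    if not (0 <= lo < hi <= 100):
        raise BandError(f"invalid percentile band {band!r}")
    p_lo = np.percentile(rank_values, lo)
    p_hi = np.percentile(rank_values, hi)
    sel = (rank_values > p_lo) & (rank_values < p_hi)
    if not sel.any():
        sel = (rank_values >= p_lo) & (rank_values <= p_hi)
    if not sel.any():
        raise BandError(f"percentile band {band!r} selects no households")
    wsum = weights[sel].sum()
    if wsum <= 0:
        raise BandError(f"zero total weight inside percentile band {band!r}")
    return float(np.sum(weights[sel] * eqfood[sel]) / wsum)


def capacity_to_pay(exp_h, food_h, se_h):
    """Household capacity to pay (non-subsistence spending).

    ``exp - se`` when subsistence is at or below actual food spending, else
    ``exp - food``; at equality both branches coincide.  May be non-positive
    for extreme households; such values are passed through (the CHE indicator
    applies its degenerate-household convention downstream).
    """
    exp_h = np.asarray(exp_h, dtype=float)
    food_h = np.asarray(food_h, dtype=float)
    se_h = np.asarray(se_h, dtype=float)
    if np.any(exp_h < 0) or np.any(food_h < 0) or np.any(se_h < 0):
        raise ValidationError("capacity_to_pay arguments must be non-negative")
    return np.where(se_h <= food_h, exp_h - se_h, exp_h - food_h)


def che_indicator(oop_h, ctp_h, threshold: float = DEFAULT_THRESHOLD):
    """OOP share of capacity to pay and the CHE flag.

    Returns ``(oopctp, cata)``.  For ``ctp > 0``: ``oopctp = oop/ctp`` and
    ``cata = 1`` iff the share equals or exceeds the threshold (boundary
    inclusive).  For ``ctp <= 0`` the share is undefined (NaN) and any positive
    OOP counts as catastrophic — the conservative "infinite burden" convention.
    """
    oop_h = np.asarray(oop_h, dtype=float)
    ctp_h = np.asarray(ctp_h, dtype=float)
    if np.any(oop_h < 0):
        raise ValidationError("out-of-pocket spending must be non-negative")
    positive = ctp_h > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        oopctp = np.where(positive, oop_h / np.where(positive, ctp_h, 1.0), np.nan)
    cata = np.where(positive, oopctp >= threshold, oop_h > 0).astype(int)
    return oopctp, cata


@dataclass
class SurveyCHE:
    """CHE chain output for one survey.

    Attributes
    ----------
    pl : float
        Poverty line (currency per equivalent adult per month).
    threshold, beta : float
        CHE cutoff and equivalence exponent used.
    band : tuple
        Percentile band used for the poverty line.
    results : pandas.DataFrame
        One row per household: household_id, foodexp, eqsize, eqfood, se, ctp,
        ctp_nonpositive, oopctp, cata, weight.
    """

    pl: float
    threshold: float
    beta: float
    band: tuple
    results: pd.DataFrame = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.results)

    @property
    def incidence(self) -> float:
        """Weighted CHE incidence in percent."""
        w = self.results["weight"].to_numpy()
        return float(100.0 * np.sum(w * self.results["cata"].to_numpy()) / np.sum(w))

    def summary(self) -> dict:
        return {
            "n_households": int(self.n),
            "poverty_line": self.pl,
            "threshold": self.threshold,
            "beta": self.beta,
            "band": list(self.band),
            "che_count": int(self.results["cata"].sum()),
            "incidence_pct": round(self.incidence, 2),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_che(
    records: pd.DataFrame,
    beta: float = DEFAULT_BETA,
    band=DEFAULT_BAND,
    threshold: float = DEFAULT_THRESHOLD,
    band_ranking: str = "food_share",
) -> SurveyCHE:
    """Apply the full CHE chain to cleaned household records.

    ``records`` needs columns household_id, food_month, exp_month, oop_month,
    hhsize and (optionally) weight.  One poverty line is computed for the whole
    survey.  ``band_ranking`` selects the variable defining the 45-55 band:
    ``"food_share"`` (WHO convention, default) or ``"expenditure"``.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must lie in (0, 1]")
    exp_h = records["exp_month"].to_numpy(dtype=float)
    food_h = records["food_month"].to_numpy(dtype=float)
    oop_h = records["oop_month"].to_numpy(dtype=float)
    hhsize = records["hhsize"].to_numpy(dtype=float)
    weight = (
        records["weight"].to_numpy(dtype=float)
        if "weight" in records.columns
        else np.ones(len(records))
    )

    foodexp = food_share(food_h, exp_h)
    eqsize = equivalized_size(hhsize, beta)
    eqfood = food_h / eqsize
    if band_ranking == "food_share":
        rank_values = foodexp
    elif band_ranking == "expenditure":
        rank_values = exp_h
    else:
        raise ValidationError(f"unknown band_ranking {band_ranking!r}")
    pl = poverty_line(rank_values, eqfood, weights=weight, band=band)
    se = pl * eqsize
    ctp = capacity_to_pay(exp_h, food_h, se)
    oopctp, cata = che_indicator(oop_h, ctp, threshold)

    results = pd.DataFrame(
        {
            "household_id": records["household_id"].to_numpy(),
            "foodexp": foodexp,
            "eqsize": eqsize,
            "eqfood": eqfood,
            "se": se,
            "ctp": ctp,
            "ctp_nonpositive": ctp <= 0,
            "oopctp": oopctp,
            "cata": cata,
            "weight": weight,
        }
    )
    return SurveyCHE(pl=pl, threshold=threshold, beta=beta, band=tuple(band), results=results)
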