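"""Synthetic household-survey generator with known CHE ground truth.

Emulates the fields of a CHARLS-style household survey — weekly food
spending, monthly consumption, annual out-of-pocket (OOP) medical spending
split into outpatient/inpatient parts, household size, householder
covariates, insurance type, and a member-level table with 14
chronic-condition answers — so that every downstream stage (cleaning, the
CHE chain, stratified tables, the logistic model) can be exercised and
validated without restricted microdata.

Mechanism
---------
Monetary fields are right-skewed like real spending data: consumption is
log-normal, the food share is Beta, and OOP is zero-inflated log-normal.
Covariates drive CHE through the OOP draw: a household's probability of its
OOP crossing the 40%-of-capacity-to-pay threshold is exactly logistic,
``expit(base_log_odds + true_beta . x)``, in the model's design terms: the
zero-OOP gate applies first, a latent Bernoulli then picks the side of the
threshold among OOP-positive households (with the conditional probability
scaled so the unconditional law is exactly logistic), and the OOP amount is
drawn from the log-normal truncated to that side.  The flag itself is never
set directly — it emerges
from the CHE equation chain downstream — but the generator-implied
``P(cata=1 | x)`` is known in closed form, which makes parameter-recovery
tests exact in expectation.

Economic quintiles and household-size classes are derived covariates, so the
generator computes them internally from its own monetary draws (same ranking
rule as the preprocess stage) when applying their effects.

Each field uses its own deterministic pseudo-random substream derived from
(seed, field name), so adding a field never perturbs earlier fields and the
same (config, seed) yields byte-identical surveys.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from . import che
from .errors import ConfigurationError
from .preprocess import DISEASE_NAMES, RawSurvey, WEEKS_PER_MONTH
from .regression import build_design_matrix, default_design_spec

# ---------------------------------------------------------------------------
# Defaults: the generator's study conditions
# ---------------------------------------------------------------------------


def default_covariate_prevalences() -> dict:
    """Categorical covariate prevalences, loosely following the marginal
    proportions of a Chinese middle-aged/older household survey; illustrative,
    not a calibration."""
    return {
        "sex": {"Female": 0.545, "Male": 0.455},
        "marital": {"Single": 0.22, "Married": 0.78},
        "residence": {"Rural": 0.70, "Urban": 0.30},
        "education": {
            "Illiterate": 0.24,
            "Primary school": 0.44,
            "Junior high school and above": 0.32,
        },
        "region": {"East": 0.32, "Central": 0.34, "West": 0.34},
        "labour": {"No": 0.40, "Yes": 0.60},
        "self_rated_health": {"Good": 0.63, "Bad": 0.37},
        "outpatient": {"No": 0.78, "Yes": 0.22},
        "inpatient": {"No": 0.755, "Yes": 0.245},
        "disabled": {"No": 0.756, "Yes": 0.244},
        "insurance": {
            "URRBMI": 0.116,
            "UEBMI": 0.152,
            "NRCMS": 0.635,
            "URBMI": 0.047,
            "Other": 0.05,
        },
    }


def default_disease_prevalences() -> dict:
    """Householder prevalence of each of the 14 chronic conditions."""
    return {
        "hypertension": 0.08,
        "dyslipidaemia": 0.03,
        "diabetes": 0.05,
        "malignant_tumour": 0.015,
        "chronic_lung_disease": 0.055,
        "liver_disease": 0.012,
        "heart_disease": 0.07,
        "stroke": 0.05,
        "kidney_disease": 0.015,
        "stomach_disease": 0.04,
        "emotional_problems": 0.006,
        "memory_disease": 0.008,
        "arthritis": 0.06,
        "asthma": 0.01,
    }


def default_true_beta() -> dict:
    """True log-odds effects on CHE, one per design-matrix term.

    Defaults mirror the odds ratios a survey of this kind reports: inpatient
    use in the past year OR 2.73, outpatient use in the past month OR 2.16,
    malignant tumour OR 2.02, and so on.  Terms not listed have effect 0.
    """
    odds = {
        "age": 1.01,  # per year
        "region[Central]": 0.77,
        "region[West]": 0.78,
        "economic_level[2]": 1.00,
        "economic_level[3]": 0.83,
        "economic_level[4]": 0.69,
        "economic_level[5]": 0.87,
        "size_class[2]": 1.08,
        "size_class[3+]": 0.70,
        "labour[Yes]": 0.82,
        "member_65[Yes]": 1.43,
        "disabled[Yes]": 1.28,
        "outpatient[Yes]": 2.16,
        "inpatient[Yes]": 2.73,
        "heart_disease[Yes]": 1.12,
        "stroke[Yes]": 1.32,
        "malignant_tumour[Yes]": 2.02,
        "chronic_lung_disease[Yes]": 1.14,
        "diabetes[Yes]": 1.13,
        "insurance[UEBMI]": 0.49,
        "insurance[NRCMS]": 0.92,
        "insurance[URBMI]": 0.56,
        "insurance[Other]": 0.45,
    }
    return {term: math.log(v) for term, v in odds.items()}


def default_household_size_probs() -> dict:
    return {1: 0.13, 2: 0.715, 3: 0.10, 4: 0.035, 5: 0.015, 6: 0.005}


@dataclass
class SyntheticConfig:
    """Generator knobs.  Defaults define the standing study conditions.

    Monetary units are currency yuan; expenditure parameters are on the log
    scale (monthly consumption median exp(7.6) ~ 2000).  ``true_beta`` maps
    design-matrix terms to log-odds effects on CHE occurrence (see module
    docstring for the mechanism); ``base_log_odds`` is the intercept.
    """

    n_households: int = 9186
    seed: int = 2018
    # monthly consumption expenditure, log scale
    exp_log_mean: float = 7.6
    exp_log_sd: float = 0.7
    # food share of consumption, Beta(alpha, beta) on (0, 1); mean 0.4
    food_share_alpha: float = 4.0
    food_share_beta: float = 6.0
    # annual OOP: zero-inflated log-normal; oop_zero_prob is the
    # (covariate-independent) probability of exactly-zero OOP
    oop_zero_prob: float = 0.25
    oop_log_mean: float = 7.0
    oop_log_sd: float = 1.5
    # householder age (years), truncated normal
    age_mean: float = 63.0
    age_sd: float = 10.0
    age_min: float = 45.0
    # CHE mechanism
    base_log_odds: float = -2.2
    true_beta: dict = field(default_factory=default_true_beta)
    # covariate distributions
    household_size_probs: dict = field(default_factory=default_household_size_probs)
    covariate_prevalences: dict = field(default_factory=default_covariate_prevalences)
    disease_prevalences: dict = field(default_factory=default_disease_prevalences)
    member_disease_scale: float = 0.4  # non-householder prevalence multiplier
    # missingness injection
    missing_food_rate: float = 0.10  # unsupplementable -> deleted downstream
    missing_oop_rate: float = 0.10  # total missing, parts present -> supplemented
    missing_oop_parts_rate: float = 0.01  # total and parts missing -> deleted
    missing_size_rate: float = 0.05  # supplemented from member rows
    # CHE chain constants the mechanism is defined against
    che_threshold: float = che.DEFAULT_THRESHOLD
    eq_beta: float = che.DEFAULT_BETA
    band: tuple = che.DEFAULT_BAND

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        for name in (
            "oop_zero_prob",
            "missing_food_rate",
            "missing_oop_rate",
            "missing_oop_parts_rate",
            "missing_size_rate",
            "member_disease_scale",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("exp_log_sd", "oop_log_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("food_share_alpha", "food_share_beta"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if abs(sum(self.household_size_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("household_size_probs must sum to 1")
        if any(p < 0 for p in self.household_size_probs.values()):
            raise ConfigurationError("household_size_probs must be non-negative")
        for cov, probs in self.covariate_prevalences.items():
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigurationError(f"covariate_prevalences[{cov}] outside [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"covariate_prevalences[{cov}] must sum to 1")
        for cond, p in self.disease_prevalences.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"disease_prevalences[{cond}] outside [0, 1]")
        valid_terms = set(default_design_spec().column_names()) - {"const"}
        unknown = set(self.true_beta) - valid_terms
        if unknown:
            raise ConfigurationError(f"unknown true_beta terms: {sorted(unknown)}")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "household_size_probs" in d:
            d["household_size_probs"] = {int(k): v for k, v in d["household_size_probs"].items()}
        if "band" in d:
            d["band"] = tuple(d["band"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Per-field substream: deterministic in (seed, stream name) only."""
    entropy = int(seed) % (2**63)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=entropy, spawn_key=(zlib.crc32(stream.encode()),))
    )


def _draw_categorical(rng, probs: dict, n: int) -> np.ndarray:
    levels = list(probs.keys())
    p = np.array([probs[lv] for lv in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=p / p.sum())


def _internal_quintile(exp_month, hhsize, household_id) -> np.ndarray:
    """Same ranking/allocation rule as preprocess.assign_economic_quintile."""
    n = len(exp_month)
    order = pd.DataFrame(
        {"pc": exp_month / hhsize, "hid": household_id}
    ).sort_values(["pc", "hid"], kind="mergesort")
    base, extra = divmod(n, 5)
    sizes = [base + (1 if g < extra else 0) for g in range(5)]
    levels = np.repeat(np.arange(1, 6), sizes)
    return pd.Series(levels, index=order.index).sort_index().to_numpy()


def _allocate_oop(rng, crosses, ctp, threshold, mu, sd) -> np.ndarray:
    """Monthly OOP from the log-normal (annual scale: mu, sd) truncated to the
    requested side of threshold*ctp.  Crossing draws land at or above the
    threshold share, non-crossing draws strictly below."""
    thresh_annual = np.log(threshold * ctp * 12.0)
    if sd == 0.0:
        point = math.exp(mu) / 12.0
        lo = threshold * ctp * (1.0 - 1e-12)
        return np.where(crosses, np.maximum(point, threshold * ctp), np.minimum(point, lo))
    z_th = (thresh_annual - mu) / sd
    F = np.clip(ndtr(z_th), 1e-12, 1.0 - 1e-12)
    u0 = rng.uniform(size=ctp.size)
    u = np.where(crosses, F + u0 * (1.0 - F), u0 * F)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return np.exp(mu + sd * ndtri(u)) / 12.0


def _draw_oop(cfg: SyntheticConfig, seed: int, prefix: str, p_true, ctp):
    """Zero-inflated OOP draw realising P(cata=1 | x) = p_true.

    The zero gate applies first (probability ``oop_zero_prob``, independent of
    covariates); among OOP-positive households a latent Bernoulli with
    probability ``p_true / (1 - oop_zero_prob)`` picks the side of the CHE
    threshold, so the unconditional crossing probability is exactly ``p_true``.
    Households whose implied conditional probability would exceed 1 are capped
    (vanishingly rare under the default effect sizes).  ``oop_zero_prob = 1``
    forces every OOP to zero, hence zero CHE incidence downstream.
    """
    n = ctp.size
    zero = _rng(seed, prefix + "oop_zero").uniform(size=n) < cfg.oop_zero_prob
    u_cross = _rng(seed, prefix + "cata_latent").uniform(size=n)
    if cfg.oop_zero_prob >= 1.0:
        return np.zeros(n, dtype=bool), np.zeros(n)
    q = np.minimum(p_true / (1.0 - cfg.oop_zero_prob), 1.0 - 1e-12)
    crosses = (~zero) & (u_cross < q)
    oop_month = _allocate_oop(
        _rng(seed, prefix + "oop"), crosses, ctp, cfg.che_threshold, cfg.oop_log_mean, cfg.oop_log_sd
    )
    return crosses, np.where(zero, 0.0, oop_month)


def generate_survey(config: SyntheticConfig) -> RawSurvey:
    """Generate one survey; deterministic in (config, config.seed).

    Returns a :class:`RawSurvey` whose ``truth`` table carries the
    generator-implied CHE probability, the latent threshold-crossing draw,
    and the internal poverty line / capacity-to-pay used by the mechanism.
    """
    config.validate()
    cfg = config
    n = cfg.n_households
    seed = cfg.seed

    household_id = np.array([f"H{i:06d}" for i in range(1, n + 1)], dtype=object)

    sizes = _rng(seed, "household_size").choice(
        np.array(sorted(cfg.household_size_probs)),
        size=n,
        p=np.array([cfg.household_size_probs[k] for k in sorted(cfg.household_size_probs)]),
    )
    age = np.clip(
        _rng(seed, "age").normal(cfg.age_mean, cfg.age_sd, size=n), cfg.age_min, 100.0
    ).round(0)

    covs = {}
    for name in sorted(cfg.covariate_prevalences):
        covs[name] = _draw_categorical(_rng(seed, f"cov:{name}"), cfg.covariate_prevalences[name], n)

    # member ages: householder plus size-1 others scattered around the head's age
    n_other = sizes - 1
    total_other = int(n_other.sum())
    other_hh = np.repeat(np.arange(n), n_other)
    other_age = np.clip(
        age[other_hh] + _rng(seed, "member_age").normal(0.0, 10.0, size=total_other),
        16.0,
        100.0,
    ).round(0)
    any65_other = np.zeros(n, dtype=bool)
    if total_other:
        any65 = pd.Series(other_age >= 65).groupby(other_hh).any()
        any65_other[any65.index.to_numpy()] = any65.to_numpy()
    member_65 = np.where((age >= 65) | any65_other, "Yes", "No")

    # 14 chronic-condition answers: householder at the configured prevalence,
    # other members at a scaled-down rate
    head_disease = {}
    other_disease = {}
    for cond in DISEASE_NAMES:
        p = cfg.disease_prevalences.get(cond, 0.0)
        head_disease[cond] = (_rng(seed, f"disease:{cond}").uniform(size=n) < p).astype(int)
        other_disease[cond] = (
            _rng(seed, f"member_disease:{cond}").uniform(size=total_other)
            < p * cfg.member_disease_scale
        ).astype(int)

    # monetary mechanism
    exp_month = np.exp(_rng(seed, "exp").normal(cfg.exp_log_mean, cfg.exp_log_sd, size=n))
    share = _rng(seed, "food_share").beta(cfg.food_share_alpha, cfg.food_share_beta, size=n)
    food_month = share * exp_month
    eqsize = sizes.astype(float) ** cfg.eq_beta
    eqfood = food_month / eqsize
    pl = che.poverty_line(share, eqfood, band=cfg.band)
    se = pl * eqsize
    ctp = np.where(se <= food_month, exp_month - se, exp_month - food_month)
    economic_level = _internal_quintile(exp_month, sizes.astype(float), household_id)

    design_records = pd.DataFrame(
        {
            "household_id": household_id,
            "age": age,
            "region": covs["region"],
            "economic_level": economic_level,
            "size_class": np.select([sizes == 1, sizes == 2], ["1", "2"], default="3+"),
            "labour": covs["labour"],
            "member_65": member_65,
            "disabled": covs["disabled"],
            "outpatient": covs["outpatient"],
            "inpatient": covs["inpatient"],
            "insurance": covs["insurance"],
        }
    )
    for cond in ("heart_disease", "stroke", "malignant_tumour", "chronic_lung_disease", "diabetes"):
        design_records[cond] = np.where(head_disease[cond] == 1, "Yes", "No")

    spec = default_design_spec()
    _, X, names = build_design_matrix(design_records, np.zeros(n), spec)
    beta_vec = np.array(
        [cfg.base_log_odds if c == "const" else cfg.true_beta.get(c, 0.0) for c in names]
    )
    p_true = expit(X @ beta_vec)
    crosses, oop_month = _draw_oop(cfg, seed, "", p_true, ctp)

    # split the annual total into outpatient/inpatient parts
    oop_annual = oop_month * 12.0
    u_split = _rng(seed, "oop_split").uniform(size=n)
    inp_share = np.where(covs["inpatient"] == "Yes", 0.3 + 0.6 * u_split, 0.3 * u_split)
    oop_inpatient_annual = inp_share * oop_annual
    oop_outpatient_annual = oop_annual - oop_inpatient_annual

    households = pd.DataFrame(
        {
            "household_id": household_id,
            "interview_month": _rng(seed, "month").integers(1, 13, size=n),
            "weight": np.ones(n),
            "food_weekly": food_month / WEEKS_PER_MONTH,
            "exp_month": exp_month,
            "oop_annual": oop_annual,
            "oop_outpatient_annual": oop_outpatient_annual,
            "oop_inpatient_annual": oop_inpatient_annual,
            "hhsize_reported": sizes.astype(float),
            "sex": covs["sex"],
            "age": age,
            "marital": covs["marital"],
            "residence": covs["residence"],
            "education": covs["education"],
            "region": covs["region"],
            "labour": covs["labour"],
            "self_rated_health": covs["self_rated_health"],
            "outpatient": covs["outpatient"],
            "inpatient": covs["inpatient"],
            "disabled": covs["disabled"],
            "member_65": member_65,
            "insurance": covs["insurance"],
        }
    )

    # inject missingness (explicit NaN, never silent zeros)
    u_food = _rng(seed, "missing_food").uniform(size=n)
    households.loc[u_food < cfg.missing_food_rate, "food_weekly"] = np.nan
    u_oop = _rng(seed, "missing_oop").uniform(size=n)
    all_missing = u_oop < cfg.missing_oop_parts_rate
    total_missing = (~all_missing) & (
        u_oop < cfg.missing_oop_parts_rate + cfg.missing_oop_rate
    )
    households.loc[total_missing, "oop_annual"] = np.nan
    households.loc[
        all_missing, ["oop_annual", "oop_outpatient_annual", "oop_inpatient_annual"]
    ] = np.nan
    u_size = _rng(seed, "missing_size").uniform(size=n)
    households.loc[u_size < cfg.missing_size_rate, "hhsize_reported"] = np.nan

    # member-level table, consistent with the true household size
    member_rows = {
        "household_id": np.concatenate([household_id, household_id[other_hh]]),
        "member_index": np.concatenate([np.zeros(n, dtype=int), np.ones(total_other, dtype=int)]),
        "is_householder": np.concatenate([np.ones(n, dtype=int), np.zeros(total_other, dtype=int)]),
        "age": np.concatenate([age, other_age]),
    }
    for cond in DISEASE_NAMES:
        member_rows[cond] = np.concatenate([head_disease[cond], other_disease[cond]])
    members = (
        pd.DataFrame(member_rows)
        .sort_values(["household_id", "member_index"], kind="mergesort")
        .reset_index(drop=True)
    )
    # give non-householder members within a household distinct indices
    members["member_index"] = members.groupby("household_id").cumcount()

    oopctp_true, cata_true = che.che_indicator(oop_month, ctp, cfg.che_threshold)
    truth = pd.DataFrame(
        {
            "household_id": household_id,
            "p_true": p_true,
            "crosses": crosses.astype(int),
            "cata_true": cata_true,
            "pl_gen": pl,
            "ctp_gen": ctp,
            "economic_level_gen": economic_level,
        }
    )

    missing_config = {
        "missing_food_rate": cfg.missing_food_rate,
        "missing_oop_rate": cfg.missing_oop_rate,
        "missing_oop_parts_rate": cfg.missing_oop_parts_rate,
        "missing_size_rate": cfg.missing_size_rate,
    }
    return RawSurvey(households=households, members=members, missing_config=missing_config, truth=truth)


def write_survey(raw: RawSurvey, household_csv, member_csv) -> None:
    """Write the two-CSV survey layout (column dictionary in README)."""
    raw.households.to_csv(household_csv, index=False)
    raw.members.to_csv(member_csv, index=False)


# ---------------------------------------------------------------------------
# Ground-truth oracle
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = (
    "age",
    "region",
    "economic_level",
    "size_class",
    "labour",
    "member_65",
    "disabled",
    "outpatient",
    "inpatient",
    "heart_disease",
    "stroke",
    "malignant_tumour",
    "chronic_lung_disease",
    "diabetes",
    "insurance",
)

_SIZE_FROM_CLASS = {"1": 1, "2": 2, "3+": 3}


def true_che_probability(
    config: SyntheticConfig,
    covariates: dict,
    n_draws: int = 100_000,
    seed_offset: int = 1,
) -> float:
    """Monte-Carlo estimate of the generator-implied P(cata=1 | covariates).

    Simulates ``n_draws`` households with the fixed covariate profile through
    the full monetary mechanism (consumption, food share, internal poverty
    line, capacity to pay, OOP allocation) and runs the CHE chain on the
    result.  This is the oracle parameter-recovery tests compare against; by
    construction it converges to ``expit(base_log_odds + true_beta . x)``.

    ``covariates`` must supply every model column (age numeric, the rest
    categorical); an optional ``"hhsize"`` overrides the representative size
    implied by ``size_class``.
    """
    config.validate()
    unknown = set(covariates) - set(_PROFILE_COLUMNS) - {"hhsize"}
    if unknown:
        raise ConfigurationError(f"unknown covariate names: {sorted(unknown)}")
    missing = set(_PROFILE_COLUMNS) - set(covariates)
    if missing:
        raise ConfigurationError(f"profile lacks covariates: {sorted(missing)}")

    cfg = config
    m = n_draws
    profile = pd.DataFrame({c: [covariates[c]] * m for c in _PROFILE_COLUMNS})
    profile.insert(0, "household_id", np.arange(m))
    spec = default_design_spec()
    _, X, names = build_design_matrix(profile, np.zeros(m), spec)
    beta_vec = np.array(
        [cfg.base_log_odds if c == "const" else cfg.true_beta.get(c, 0.0) for c in names]
    )
    p = expit(X @ beta_vec)

    hhsize = float(covariates.get("hhsize", _SIZE_FROM_CLASS[covariates["size_class"]]))
    seed = cfg.seed + seed_offset
    exp_month = np.exp(_rng(seed, "mc:exp").normal(cfg.exp_log_mean, cfg.exp_log_sd, size=m))
    share = _rng(seed, "mc:food_share").beta(cfg.food_share_alpha, cfg.food_share_beta, size=m)
    food_month = share * exp_month
    eqsize = hhsize**cfg.eq_beta
    pl = che.poverty_line(share, food_month / eqsize, band=cfg.band)
    se = pl * eqsize
    ctp = np.where(se <= food_month, exp_month - se, exp_month - food_month)
    _, oop_month = _draw_oop(cfg, seed, "mc:", p, ctp)
    _, cata = che.che_indicator(oop_month, ctp, cfg.che_threshold)
    return float(np.mean(cata))
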