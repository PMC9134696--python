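"""End-to-end pipeline: generate/ingest -> clean -> CHE chain -> tables -> model.

One call, :func:`run_pipeline`, executes every stage and writes a
reproducible report bundle: the survey CSVs (when synthetic), the exclusion
log, per-household CHE results, stratified incidence tables, the
regression table (term, reference, OR, CI, p), a diagnostics JSON
(Hosmer-Lemeshow, VIFs, convergence), a survey summary JSON and a run
manifest whose row counts reconcile with the exclusion log.  Identical
configuration and seed give byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, che
from .errors import ConfigurationError
from .preprocess import (
    RawSurvey,
    assign_economic_quintile,
    clean_records,
    deflate_to_monthly,
    flag_chronic_household,
    read_survey,
)
from .regression import (
    build_design_matrix,
    default_design_spec,
    fit_logistic,
    hosmer_lemeshow,
    odds_ratios,
    vif_by_term,
)
from .stratify import disease_condition_tables, incidence_table, quintile_summary
from .synthetic import SyntheticConfig, generate_survey, write_survey

logger = logging.getLogger("chesurvey")

#: covariates the descriptive incidence tables are stratified by
TABLE_STRATIFIERS = (
    "sex",
    "age_group",
    "residence",
    "education",
    "marital",
    "size_class",
    "region",
    "economic_level",
    "insurance",
)


@dataclass
class PipelineConfig:
    """Pipeline settings.  Exactly one of ``synthetic`` or the two input CSV
    paths must be given."""

    output_dir: str
    synthetic: SyntheticConfig | None = None
    household_csv: str | None = None
    member_csv: str | None = None
    cpi_index: dict | None = None  # interview month -> CPI factor; None = identity
    beta: float = che.DEFAULT_BETA
    threshold: float = che.DEFAULT_THRESHOLD
    band: tuple = che.DEFAULT_BAND
    band_ranking: str = "food_share"
    extended_design: bool = False
    fit_model: bool = True  # False: stop after the CHE chain and tables
    fit_on_chronic_only: bool = True
    weights_column: str | None = None
    seed: int | None = None  # overrides synthetic.seed when given

    def validate(self) -> None:
        has_files = self.household_csv is not None and self.member_csv is not None
        if (self.synthetic is None) == (not has_files):
            raise ConfigurationError(
                "exactly one of {synthetic config, household+member CSV paths} required"
            )
        if not (0 < self.threshold <= 1):
            raise ConfigurationError("threshold must lie in (0, 1]")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- ingest or simulate -------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed is not None:
            syn = dataclasses.replace(syn, seed=config.seed)
        logger.info("generating synthetic survey: n=%d seed=%d", syn.n_households, syn.seed)
        raw: RawSurvey = generate_survey(syn)
        write_survey(raw, outdir / "survey_households.csv", outdir / "survey_members.csv")
    else:
        logger.info("reading survey from %s / %s", config.household_csv, config.member_csv)
        raw = read_survey(config.household_csv, config.member_csv)

    # --- preprocess ---------------------------------------------------------
    deflated = deflate_to_monthly(raw, config.cpi_index)
    records, exclusion_log = clean_records(deflated)
    _csv(exclusion_log.to_frame(), outdir / "exclusion_log.csv")

    chronic = flag_chronic_household(deflated.members)
    records = records.merge(chronic, on="household_id", how="left")
    records["chronic_household"] = records["chronic_household"].fillna(False).astype(bool)
    for col in chronic.columns:
        if col != "chronic_household" and records[col].isna().any():
            records.loc[records[col].isna(), col] = "No" if col != "disease_count_class" else "none"
    records = assign_economic_quintile(records)
    if config.weights_column is not None:
        records["weight"] = records[config.weights_column].astype(float)
    _csv(records, outdir / "households_clean.csv")

    # --- CHE chain (poverty line on the full cleaned sample) ----------------
    survey_che = che.run_che(
        records,
        beta=config.beta,
        band=config.band,
        threshold=config.threshold,
        band_ranking=config.band_ranking,
    )
    _csv(survey_che.results, outdir / "che_results.csv")
    analysed = records.merge(
        survey_che.results[["household_id", "oopctp", "cata"]], on="household_id"
    )
    chronic_sub = analysed.loc[analysed["chronic_household"]]

    summary = survey_che.summary()
    if len(chronic_sub):
        w = chronic_sub["weight"].to_numpy()
        summary["chronic_subsample"] = {
            "n_households": int(len(chronic_sub)),
            "che_count": int(chronic_sub["cata"].sum()),
            "incidence_pct": round(float(100.0 * np.sum(w * chronic_sub["cata"]) / np.sum(w)), 2),
        }
    _write_json(outdir / "summary.json", summary)

    # --- stratified tables (chronic subsample, as in the study design) ------
    table_pop = chronic_sub if len(chronic_sub) else analysed
    index = {}
    for strat in TABLE_STRATIFIERS:
        if strat not in table_pop.columns:
            continue
        t = incidence_table(table_pop, strat)
        fname = f"incidence_{strat}.csv"
        _csv(t.to_frame(), outdir / fname)
        index[strat] = {
            "file": fname,
            "chi_square": t.chi_square,
            "df": t.df,
            "p_value": t.p_value,
        }
    disease_tables = disease_condition_tables(analysed)
    if disease_tables:
        combined = []
        for t in disease_tables:
            frame = t.to_frame()
            frame.insert(1, "scope", t.scope)
            frame["chi_square"] = np.nan if t.chi_square is None else t.chi_square
            frame["df"] = np.nan if t.df is None else t.df
            frame["p_value"] = np.nan if t.p_value is None else t.p_value
            combined.append(frame)
        _csv(pd.concat(combined, ignore_index=True), outdir / "incidence_disease_conditions.csv")
        index["disease_conditions"] = {"file": "incidence_disease_conditions.csv"}
    _csv(quintile_summary(analysed), outdir / "quintile_summary.csv")
    index["quintile_summary"] = {"file": "quintile_summary.csv"}
    _write_json(outdir / "tables_index.json", index)

    # --- logistic model ------------------------------------------------------
    n_fit = 0
    if config.fit_model:
        fit_pop = chronic_sub if (config.fit_on_chronic_only and len(chronic_sub)) else analysed
        n_fit = len(fit_pop)
        spec = default_design_spec(extended=config.extended_design)
        y, X, names = build_design_matrix(fit_pop, fit_pop["cata"].to_numpy(), spec)
        fit = fit_logistic(y, X, columns=names)
        ors = odds_ratios(fit)
        reference = {}
        for term in spec.terms:
            if term.kind == "categorical":
                for name in term.column_names():
                    reference[name] = str(term.reference)
        ors.insert(1, "reference", [reference.get(t, "") for t in ors["term"]])
        _csv(ors, outdir / "regression_table.csv")

        hl_stat, hl_df, hl_p = hosmer_lemeshow(y, fit.fitted, groups=10)
        vifs = vif_by_term(X, names)
        diagnostics = {
            "n_fit": int(n_fit),
            "converged": bool(fit.converged),
            "n_iter": int(fit.n_iter),
            "log_likelihood": fit.log_likelihood,
            "hosmer_lemeshow": {"statistic": hl_stat, "df": hl_df, "p_value": hl_p},
            "vif": {k: (None if np.isinf(v) else float(v)) for k, v in vifs.items()},
        }
        _write_json(outdir / "diagnostics.json", diagnostics)

    # --- manifest -----------------------------------------------------------
    cfg_echo = dataclasses.asdict(config)
    cfg_echo.pop("output_dir", None)  # keep bundles byte-identical across directories
    if cfg_echo.get("synthetic") is not None:
        cfg_echo["synthetic"]["band"] = list(cfg_echo["synthetic"]["band"])
        cfg_echo["synthetic"]["household_size_probs"] = {
            str(k): v for k, v in cfg_echo["synthetic"]["household_size_probs"].items()
        }
    cfg_echo["band"] = list(cfg_echo["band"])
    manifest = {
        "package_version": __version__,
        "config": cfg_echo,
        "seed": config.seed if config.seed is not None else getattr(config.synthetic, "seed", None),
        "counts": {
            "raw": int(exclusion_log.initial),
            "excluded": int(exclusion_log.initial - exclusion_log.final),
            "clean": int(exclusion_log.final),
            "chronic_subsample": int(len(chronic_sub)),
            "fitted": int(n_fit),
        },
        "exclusion_log": [
            {"rule": r, "removed": rem, "remaining": left} for r, rem, left in exclusion_log.rows
        ],
        "incidence_pct": summary["incidence_pct"],
    }
    _write_json(outdir / "manifest.json", manifest)
    logger.info(
        "pipeline done: n=%d clean, incidence %.2f%%", exclusion_log.final, summary["incidence_pct"]
    )
    return manifest
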