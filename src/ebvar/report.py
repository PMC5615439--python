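"""Report assembly: every output surface of the analysis from one config.

`run_report` reads a cohort (subject + daily tables), applies the valid-day
wear filter, and writes:

* ``reliability.csv`` — per outcome: single-day ICC, Spearman-Brown days
  needed (real and whole), intra-individual CV with 95% CI;
* ``day_of_week_means.csv`` / ``day_of_week_contrasts.csv`` — adjusted
  daily means, all pairwise day contrasts, and the highest-lowest day
  effect per outcome;
* ``mbi_effects.csv`` — covariate (2-SD / sex) and measurement-order
  effects with their magnitude-based-inference classification;
* ``energy_balance.csv`` — mean intake by macronutrient and mean
  expenditure by component, kcal/day and percent shares;
* ``provenance.json`` — config echo, library versions and model
  convergence diagnostics.

Every number comes from one library operation — the report layer only
arranges tables.  Percent columns are rounded to one decimal in ``*_1dp``
display columns; the unrounded values stay in their own columns, so two
runs on identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .components import component_shares, derive_components
from .errors import EbvarError
from .io_model import (
    OUTCOME_COLUMNS,
    filter_valid_days,
    read_daily_table,
    read_subject_table,
    records_to_frame,
)
from .mbi import covariate_effect, day_of_week_effects, effects_frame, order_effect
from .reliability import (
    DEFAULT_COVARIATES,
    ModelSpec,
    auto_offset,
    fit_variance_model,
    reliability_frame,
    reliability_table,
)

logger = logging.getLogger(__name__)

_MBI_COVARIATES = ("age", "injury_level", "wear_time", "sex")


@dataclass
class RunConfig:
    daily_table: Path
    subject_table: Path
    out_dir: Path
    wear_cutoff: float = 0.80
    apply_wear_filter: bool = True
    target_icc: float = 0.80
    outcomes: tuple[str, ...] | None = None  # None = all outcome columns present
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    log_offsets: Mapping[str, float] = field(default_factory=dict)
    contrasts: tuple[str, ...] = _MBI_COVARIATES + ("order",)
    seed: int | None = None  # echoed into provenance for simulate passthrough

    def __post_init__(self) -> None:
        if not 0.0 < self.target_icc < 1.0:
            raise EbvarError(f"target_icc must be in (0, 1), got {self.target_icc}")
        for p in (self.daily_table, self.subject_table):
            if not Path(p).exists():
                raise EbvarError(f"input path does not exist: {p}")


class ReportStageError(EbvarError):
    """Wraps a stage failure with the stage name for the CLI exit path."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_cols(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[f"{c}_1dp"] = df[c].round(1)
    return df


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline; returns the paths written, keyed by surface."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    provenance: dict = {
        "package": {"name": "ebvar", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            "daily_table": str(config.daily_table),
            "subject_table": str(config.subject_table),
            "wear_cutoff": config.wear_cutoff,
            "apply_wear_filter": config.apply_wear_filter,
            "target_icc": config.target_icc,
            "covariates": list(config.covariates),
            "log_offsets": dict(config.log_offsets),
            "seed": config.seed,
        },
        "models": {},
    }
    import statsmodels

    provenance["versions"]["statsmodels"] = statsmodels.__version__

    stage = "load"
    try:
        subjects = read_subject_table(config.subject_table)
        records = read_daily_table(config.daily_table)
        n_raw = len(records)
        if config.apply_wear_filter:
            records = filter_valid_days(records, config.wear_cutoff)
        provenance["config"]["n_records_raw"] = n_raw
        provenance["config"]["n_records_valid"] = len(records)
        df = records_to_frame(records, subjects)
        outcomes = (
            list(config.outcomes)
            if config.outcomes
            else [c for c in OUTCOME_COLUMNS if c in df.columns]
        )
    except Exception as exc:
        raise ReportStageError(stage, exc) from exc

    stage = "reliability"
    try:
        rel = reliability_table(
            df,
            None,
            outcomes,
            covariates=config.covariates,
            target_icc=config.target_icc,
            log_offsets=config.log_offsets,
        )
        rel_df = _round_cols(
            reliability_frame(rel), ["cv_mean_pct", "cv_lo_pct", "cv_hi_pct"]
        )
        paths["reliability"] = out / "reliability.csv"
        rel_df.to_csv(paths["reliability"], index=False)
    except Exception as exc:
        raise ReportStageError(stage, exc) from exc

    stage = "day_of_week"
    try:
        mean_rows, contrast_rows = [], []
        fits = {}
        for outcome in outcomes:
            sub = df.dropna(subset=[outcome])
            offset = config.log_offsets.get(outcome, auto_offset(sub[outcome].to_numpy()))
            spec = ModelSpec(
                outcome=outcome,
                fixed_covariates=tuple(config.covariates),
                log_offset=float(offset),
            )
            vc = fit_variance_model(df, None, spec)
            fits[outcome] = vc
            provenance["models"][outcome] = {
                "converged": vc.converged,
                "n_obs": vc.n_obs,
                "n_subjects": vc.n_subjects,
                "sigma2_between": vc.sigma2_between,
                "sigma2_within": vc.sigma2_within,
                "log_offset": float(offset),
                "df_resid": vc.df_resid,
            }
            if "day_of_week" not in config.covariates:
                continue
            dow = day_of_week_effects(vc)
            m = dow.adjusted_means.copy()
            m.insert(0, "outcome", outcome)
            mean_rows.append(m)
            c = dow.pairwise.copy()
            c.insert(0, "outcome", outcome)
            contrast_rows.append(c)
            hl = dow.highest_lowest
            contrast_rows.append(
                pd.DataFrame(
                    [
                        {
                            "outcome": outcome,
                            "day_a": dow.highest_day,
                            "day_b": dow.lowest_day,
                            "effect_pct": hl.effect_pct,
                            "lo95_pct": hl.ci95_pct[0],
                            "hi95_pct": hl.ci95_pct[1],
                            "p_value": np.nan,
                            "contrast": "highest-lowest",
                            "clarity": hl.clarity,
                            "qualifier": hl.qualifier,
                        }
                    ]
                )
            )
        if mean_rows:
            means = _round_cols(pd.concat(mean_rows, ignore_index=True), [])
            paths["day_of_week_means"] = out / "day_of_week_means.csv"
            means.to_csv(paths["day_of_week_means"], index=False)
            contrasts = pd.concat(contrast_rows, ignore_index=True)
            if "contrast" in contrasts.columns:
                contrasts["contrast"] = contrasts["contrast"].fillna("pairwise")
            contrasts = _round_cols(contrasts, ["effect_pct", "lo95_pct", "hi95_pct"])
            paths["day_of_week_contrasts"] = out / "day_of_week_contrasts.csv"
            contrasts.to_csv(paths["day_of_week_contrasts"], index=False)
    except Exception as exc:
        raise ReportStageError(stage, exc) from exc

    stage = "mbi"
    try:
        effects = []
        labels = []
        for outcome in outcomes:
            vc = fits[outcome]
            if vc.sigma2_between <= 0:
                logger.warning(
                    "outcome %s: no between-subject variance; MBI skipped", outcome
                )
                continue
            for cov in config.contrasts:
                if cov == "order":
                    if "order_index" in config.covariates:
                        effects.append(order_effect(vc))
                        labels.append(outcome)
                elif cov in config.covariates:
                    effects.append(covariate_effect(vc, cov))
                    labels.append(outcome)
        eff_df = effects_frame(effects)
        eff_df.insert(0, "outcome", labels)
        eff_df = _round_cols(eff_df, ["effect_pct", "lo95_pct", "hi95_pct"])
        paths["mbi_effects"] = out / "mbi_effects.csv"
        eff_df.to_csv(paths["mbi_effects"], index=False)
    except Exception as exc:
        raise ReportStageError(stage, exc) from exc

    stage = "energy_balance"
    try:
        eb = energy_balance_summary(df)
        eb = _round_cols(eb, ["mean_kcal", "share_pct"])
        paths["energy_balance"] = out / "energy_balance.csv"
        eb.to_csv(paths["energy_balance"], index=False)
    except Exception as exc:
        raise ReportStageError(stage, exc) from exc

    stage = "provenance"
    try:
        paths["provenance"] = out / "provenance.json"
        paths["provenance"].write_text(json.dumps(provenance, indent=2, sort_keys=True))
    except Exception as exc:
        raise ReportStageError(stage, exc) from exc
    return paths


def energy_balance_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean daily energy flux by component, kcal/day and percent shares.

    Expenditure components are derived per subject-day from TEE and the
    subject's RMR, averaged within subject and then across subjects (each
    participant counts once).  Intake macronutrient kcal are the daily
    intake times the macro's percent share, averaged the same way.
    """
    rows = []
    if "tee_kcal" in df.columns and "rmr" in df.columns:
        per_subj = []
        for _, grp in df.dropna(subset=["tee_kcal"]).groupby("subject_id"):
            parts = [
                derive_components(t, r)
                for t, r in zip(grp["tee_kcal"], grp["rmr"])
            ]
            per_subj.append(
                {
                    "tee": np.mean([p.tee for p in parts]),
                    "rmr": np.mean([p.rmr for p in parts]),
                    "dit": np.mean([p.dit for p in parts]),
                    "paee": np.mean([p.paee for p in parts]),
                }
            )
        ps = pd.DataFrame(per_subj)
        mean_tee = float(ps["tee"].mean())
        shares = component_shares(
            derive_components(mean_tee, float(ps["rmr"].mean()))
        )
        for comp, share in zip(("rmr", "dit", "paee"), shares):
            rows.append(
                {
                    "side": "expenditure",
                    "component": comp,
                    "mean_kcal": float(ps[comp].mean()),
                    "share_pct": share,
                }
            )
        rows.append(
            {"side": "expenditure", "component": "tee", "mean_kcal": mean_tee, "share_pct": 100.0}
        )
    if "intake_kcal" in df.columns:
        sub = df.dropna(subset=["intake_kcal"])
        macro_cols = {
            "carbohydrate": "carb_pct",
            "fat": "fat_pct",
            "protein": "protein_pct",
            "alcohol": "alcohol_pct",
        }
        per_subj = sub.groupby("subject_id").apply(
            lambda g: pd.Series(
                {
                    "intake": g["intake_kcal"].mean(),
                    **{
                        name: (g["intake_kcal"] * g[col] / 100.0).mean()
                        for name, col in macro_cols.items()
                        if col in g.columns
                    },
                }
            ),
            include_groups=False,
        )
        mean_intake = float(per_subj["intake"].mean())
        for name in macro_cols:
            if name in per_subj.columns:
                kcal = float(per_subj[name].mean())
                rows.append(
                    {
                        "side": "intake",
                        "component": name,
                        "mean_kcal": kcal,
                        "share_pct": 100.0 * kcal / mean_intake,
                    }
                )
        rows.append(
            {"side": "intake", "component": "total", "mean_kcal": mean_intake, "share_pct": 100.0}
        )
    return pd.DataFrame(rows, columns=["side", "component", "mean_kcal", "share_pct"])
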