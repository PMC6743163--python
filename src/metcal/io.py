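"""Cohort file readers/writers, config loading and the two study drivers.

CSV dialect is fixed: comma-separated, UTF-8, '.' decimal, header row
required, missing values as empty fields.  Activity column headers
declare their unit (``_h_wk`` hours/week, ``_min_wk`` minutes/week,
``_h_day`` hours/day); the loaders normalise everything to hours.
Duplicate ids in a validation cohort are two-season replicates and are
averaged at load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import PairedTee, compute_agreement
from .cohort import (
    BaselineRecord,
    BaselineRoster,
    apply_exclusions,
    anova_tukey,
    group_summaries,
    grouped_values,
    jonckheere_terpstra,
    pairwise_mannwhitney_bonferroni,
)
from .energy import (
    ActivityProfile,
    BmrReferenceTable,
    MetSet,
    Participant,
    ValidationRecord,
    questionnaire_tee,
)
from .inference import (
    McmcConfig,
    PriorSpec,
    run_mcmc,
    summarize_posterior,
)

logger = logging.getLogger("metcal")


class SchemaError(ValueError):
    """The file does not match the declared cohort schema."""


@dataclass
class RowError:
    line: int  # 1-based line number in the file (header is line 1)
    message: str


VALIDATION_COLUMNS = (
    "id",
    "age",
    "sex",
    "weight_kg",
    "height_cm",
    "sleep_h_day",
    "pa1_sit_h_wk",
    "pa2_stand_h_wk",
    "pa3_walk_h_wk",
    "pa4_heavy_h_wk",
    "pa5_mod_min_wk",
    "pa6_vig_min_wk",
    "pa7_vvig_min_wk",
    "accelerometer_tee_kcal_day",
)

BASELINE_COLUMNS = (
    "id",
    "age",
    "sex",
    "weight_kg",
    "height_cm",
    "sleep_h_day",
    "pa1_sit_h_wk",
    "pa2_stand_h_wk",
    "pa3_walk_h_wk",
    "pa4_heavy_h_wk",
    "pa5_mod_min_wk",
    "pa6_vig_min_wk",
    "pa7_vvig_min_wk",
    "pregnant",
    "has_anthropometry",
    "has_activity_responses",
)

_PA_COLUMNS = (
    "pa1_sit_h_wk",
    "pa2_stand_h_wk",
    "pa3_walk_h_wk",
    "pa4_heavy_h_wk",
    "pa5_mod_min_wk",
    "pa6_vig_min_wk",
    "pa7_vvig_min_wk",
)


def _unit_factor(column: str) -> float:
    """Hours per declared unit of the column header."""
    if column.endswith("_min_wk"):
        return 1.0 / 60.0
    return 1.0


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_validation_cohort(
    path,
) -> tuple[list[ValidationRecord], list[RowError]]:
    """Read a validation-cohort CSV into typed, unit-normalised records.

    Returns (records, row_errors); malformed rows are skipped and
    reported with their 1-based file line numbers.  Duplicate ids
    (two-season participants) are averaged into a single record.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    _require_columns(df, VALIDATION_COLUMNS, path)

    numeric = [c for c in VALIDATION_COLUMNS if c not in ("id", "sex")]
    errors: list[RowError] = []
    parsed = df.copy()
    for c in numeric:
        parsed[c] = pd.to_numeric(parsed[c], errors="coerce")
    bad = parsed[numeric].isna().any(axis=1)
    for idx in parsed.index[bad]:
        bad_cols = [c for c in numeric if pd.isna(parsed.loc[idx, c])]
        errors.append(
            RowError(line=int(idx) + 2, message=f"non-numeric or missing: {bad_cols}")
        )
    parsed = parsed[~bad]

    # two-season participants: average replicate rows per id
    agg = {c: "mean" for c in numeric}
    agg["sex"] = "first"
    parsed = parsed.groupby("id", sort=False, as_index=False).agg(agg)

    records = []
    for _, row in parsed.iterrows():
        participant = Participant(
            id=str(row["id"]),
            age=int(round(row["age"])),
            sex=str(row["sex"]),
            weight=float(row["weight_kg"]),
            height=float(row["height_cm"]),
        )
        hours = [float(row[c]) * _unit_factor(c) for c in _PA_COLUMNS]
        profile = ActivityProfile(
            sleep_hours_per_day=float(row["sleep_h_day"]),
            work_hours=tuple(hours[:4]),
            offduty_hours=tuple(hours[4:]),
        )
        records.append(
            ValidationRecord(
                participant=participant,
                profile=profile,
                accelerometer_tee=float(row["accelerometer_tee_kcal_day"]),
            )
        )
    if errors:
        logger.warning("load_cohort: skipped %d malformed row(s)", len(errors))
    return records, errors


def write_validation_cohort(records: Sequence[ValidationRecord], path) -> None:
    rows = []
    for rec in records:
        weekly = rec.profile.weekly_hours()
        rows.append(
            {
                "id": rec.participant.id,
                "age": rec.participant.age,
                "sex": rec.participant.sex,
                "weight_kg": rec.participant.weight,
                "height_cm": rec.participant.height,
                "sleep_h_day": rec.profile.sleep_hours_per_day,
                "pa1_sit_h_wk": weekly[0],
                "pa2_stand_h_wk": weekly[1],
                "pa3_walk_h_wk": weekly[2],
                "pa4_heavy_h_wk": weekly[3],
                "pa5_mod_min_wk": weekly[4] * 60.0,
                "pa6_vig_min_wk": weekly[5] * 60.0,
                "pa7_vvig_min_wk": weekly[6] * 60.0,
                "accelerometer_tee_kcal_day": rec.accelerometer_tee,
            }
        )
    pd.DataFrame(rows, columns=list(VALIDATION_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_baseline_roster(roster: BaselineRoster, path) -> None:
    rows = []
    for rec in roster:
        p = rec.participant
        weekly = rec.profile.weekly_hours() if rec.profile is not None else [np.nan] * 7
        rows.append(
            {
                "id": p.id,
                "age": p.age,
                "sex": p.sex,
                "weight_kg": p.weight,
                "height_cm": p.height,
                "sleep_h_day": (
                    rec.profile.sleep_hours_per_day if rec.profile else np.nan
                ),
                "pa1_sit_h_wk": weekly[0],
                "pa2_stand_h_wk": weekly[1],
                "pa3_walk_h_wk": weekly[2],
                "pa4_heavy_h_wk": weekly[3],
                "pa5_mod_min_wk": weekly[4] * 60.0 if rec.profile else np.nan,
                "pa6_vig_min_wk": weekly[5] * 60.0 if rec.profile else np.nan,
                "pa7_vvig_min_wk": weekly[6] * 60.0 if rec.profile else np.nan,
                "pregnant": int(p.pregnant),
                "has_anthropometry": int(p.has_anthropometry),
                "has_activity_responses": int(p.has_activity_responses),
            }
        )
    pd.DataFrame(rows, columns=list(BASELINE_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def load_baseline_roster(path) -> BaselineRoster:
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    _require_columns(df, BASELINE_COLUMNS, path)
    records = []
    for _, row in df.iterrows():
        has_anthro = bool(int(row["has_anthropometry"]))
        has_activity = bool(int(row["has_activity_responses"]))
        participant = Participant(
            id=str(row["id"]),
            age=int(round(row["age"])),
            sex=str(row["sex"]),
            weight=float(row["weight_kg"]) if has_anthro else None,
            height=float(row["height_cm"]) if has_anthro else None,
            pregnant=bool(int(row["pregnant"])),
            has_anthropometry=has_anthro,
            has_activity_responses=has_activity,
        )
        profile = None
        if has_activity:
            hours = [float(row[c]) * _unit_factor(c) for c in _PA_COLUMNS]
            profile = ActivityProfile(
                sleep_hours_per_day=float(row["sleep_h_day"]),
                work_hours=tuple(hours[:4]),
                offduty_hours=tuple(hours[4:]),
            )
        records.append(BaselineRecord(participant=participant, profile=profile))
    return BaselineRoster(records=records)


def load_run_config(path) -> dict:
    """Load a YAML or JSON run-configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def prior_spec_from_dict(cfg: dict) -> PriorSpec:
    if "shape" in cfg and "rate" in cfg:
        return PriorSpec(
            shape=np.asarray(cfg["shape"], float),
            rate=np.asarray(cfg["rate"], float),
            truncate=bool(cfg.get("truncate", False)),
            sigma_prior_scale=float(cfg.get("sigma_prior_scale", 300.0)),
            sigma_fixed=cfg.get("sigma_fixed"),
        )
    return PriorSpec.default(
        shape=float(cfg.get("common_shape", 4.0)),
        truncate=bool(cfg.get("truncate", False)),
        sigma_prior_scale=float(cfg.get("sigma_prior_scale", 300.0)),
        sigma_fixed=cfg.get("sigma_fixed"),
    )


def mcmc_config_from_dict(cfg: dict) -> McmcConfig:
    return McmcConfig(
        n_burnin=int(cfg.get("n_burnin", 1000)),
        n_keep=int(cfg.get("n_keep", 10000)),
        seed=int(cfg.get("seed", 0)),
        adapt_window=int(cfg.get("adapt_window", 50)),
        initial_mets=cfg.get("initial_mets"),
        initial_sigma=float(cfg.get("initial_sigma", 200.0)),
        proposal_scales=cfg.get("proposal_scales"),
    )


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_study1(
    records: Sequence[ValidationRecord],
    outdir,
    priors: Optional[PriorSpec] = None,
    mcmc_config: Optional[McmcConfig] = None,
    table: Optional[BmrReferenceTable] = None,
) -> dict:
    """Calibration workflow: MCMC MET estimation, posterior summary, and
    agreement panels under the posterior-mean and midrange MET sets.

    Writes ``chain.csv``, ``posterior.json``, ``agreement_estimated.json``
    and ``agreement_midrange.json`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = mcmc_config or McmcConfig()
    logger.info("study1: n=%d seed=%d", len(records), cfg.seed)

    chain = run_mcmc(records, priors=priors, config=cfg, table=table)
    chain.to_frame().to_csv(outdir / "chain.csv", index=False, float_format="%.10g")
    summary = summarize_posterior(chain)
    _write_json(summary.to_dict(), outdir / "posterior.json")

    met_sets = {
        "estimated": summary.met_set(label="estimated"),
        "midrange": MetSet.midrange(),
    }
    reports = {}
    for label, mets in met_sets.items():
        pairs = [
            PairedTee(
                id=rec.participant.id,
                questionnaire_tee=questionnaire_tee(
                    rec.participant, rec.profile, mets, table
                ),
                accelerometer_tee=rec.accelerometer_tee,
            )
            for rec in records
        ]
        report = compute_agreement(pairs)
        _write_json(report.to_dict(), outdir / f"agreement_{label}.json")
        reports[label] = report
    return {
        "chain": chain,
        "posterior": summary,
        "agreement": reports,
        "paths": {
            "chain": outdir / "chain.csv",
            "posterior": outdir / "posterior.json",
            "agreement_estimated": outdir / "agreement_estimated.json",
            "agreement_midrange": outdir / "agreement_midrange.json",
        },
    }


def run_study2(
    roster: BaselineRoster,
    outdir,
    met_sets: Optional[Sequence[MetSet]] = None,
    table: Optional[BmrReferenceTable] = None,
) -> dict:
    """Cohort workflow: exclusions, per-age-group TEE/MVPA summaries under
    each MET set, and the trend/comparison test battery.

    Writes ``exclusions.json``, ``group_summaries.csv`` and ``tests.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    met_sets = list(met_sets) if met_sets is not None else [
        MetSet.estimated(),
        MetSet.midrange(),
    ]
    retained, report = apply_exclusions(roster)
    logger.info(
        "study2: input=%d retained=%d", report.n_input, report.n_retained
    )
    _write_json(report.to_dict(), outdir / "exclusions.json")

    summaries = []
    tests: dict[str, dict] = {}
    for mets in met_sets:
        summaries.append(group_summaries(retained, mets, table))
        labels, tee_groups = grouped_values(retained, mets, "tee", table)
        _, mvpa_groups = grouped_values(retained, mets, "mvpa", table)
        f_stat, p_anova, tukey = anova_tukey(tee_groups, labels=labels)
        jt = jonckheere_terpstra(mvpa_groups, method="asymptotic")
        mw = pairwise_mannwhitney_bonferroni(mvpa_groups, labels=labels)
        tests[mets.label] = {
            "tee_anova": {"F": f_stat, "p": p_anova},
            "tee_tukey": tukey.to_dict(orient="records"),
            "mvpa_jonckheere_terpstra": {
                "statistic": jt.statistic,
                "z": jt.z,
                "p": jt.p,
            },
            "mvpa_mannwhitney_bonferroni": mw.to_dict(orient="records"),
        }
    summary_frame = pd.concat(summaries, ignore_index=True)
    summary_frame.to_csv(
        outdir / "group_summaries.csv", index=False, float_format="%.10g"
    )
    _write_json(tests, outdir / "tests.json")
    return {
        "exclusions": report,
        "group_summaries": summary_frame,
        "tests": tests,
        "paths": {
            "exclusions": outdir / "exclusions.json",
            "group_summaries": outdir / "group_summaries.csv",
            "tests": outdir / "tests.json",
        },
    }
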