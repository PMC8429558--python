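"""End-to-end study pipeline over a cohort CSV.

Runs, in order: exclusion filtering, metabolic profiling, the four-cell
nutrition x metabolism stratification, group-comparison tables, the
Kaplan-Meier / log-rank stratification suite, time-dependent ROC cut-off
selection for the BMM index, and multivariable Cox models from both time
origins. Every analysis deletes missing values pairwise and records the
per-analysis n; degenerate strata are skipped with a logged warning rather
than failing the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import Thresholds, MetabolicProfiler, FLAG_COLUMNS
from .groupstats import compare_groups
from .survival import km_estimate, logrank_test, cox_fit, survival_from
from .tdroc import td_roc, select_cutoff

logger = logging.getLogger("alsmet")

__all__ = ["StudyConfig", "StudyResult", "exclusion_filter", "run_study",
           "read_cohort", "COHORT_COLUMNS"]

#: Cohort CSV schema (PatientRecord fields, in column order).
COHORT_COLUMNS = [
    "patient_id", "age", "sex", "height", "premorbid_weight",
    "admission_weight", "months_since_onset", "months_since_first_visit",
    "alsfrs_r", "bulbar_onset", "vo2", "vco2", "lstm", "body_fat_pct",
    "smi", "fbs", "ldl", "pef_pct", "vc_pct", "peg", "nppv",
    "followup_months_from_onset", "event",
]

_REQUIRED_COLUMNS = ["patient_id", "height", "admission_weight",
                     "followup_months_from_onset", "event"]

#: Comparison variables in the style of the two published summary tables.
TABLE1_VARIABLES = [
    "age", "sex_female", "premorbid_bmi", "bmi", "delta_bmi",
    "excess_weight_loss", "months_since_onset", "months_since_first_visit",
    "alsfrs_r", "delta_alsfrs", "bulbar_onset", "fbs", "ldl", "pef_pct",
    "vc_pct", "body_fat_pct", "lstm", "mree_per_lstm", "mree_per_pree",
    "low_rq", "smi", "peg", "nppv",
]
TABLE2_VARIABLES = [
    "age", "sex_female", "bmi", "delta_bmi", "excess_weight_loss",
    "months_since_onset", "alsfrs_r", "delta_alsfrs", "bulbar_onset",
    "ldl", "vc_pct", "mree_per_pree", "low_rq", "high_fat", "lstm",
    "smi", "peg", "nppv", "event",
]

DEFAULT_COX_COVARIATES = ("high_bmm", "age", "alsfrs_r",
                          "excess_weight_loss", "bulbar_onset", "vc_pct")

#: KM / log-rank stratifications: name -> (subset flag or None, value, group flag)
KM_STRATIFICATIONS = {
    "metabolism_all": (None, None, "hypermetabolic"),
    "metabolism_normal_weight": ("malnourished", False, "hypermetabolic"),
    "metabolism_malnutrition": ("malnourished", True, "hypermetabolic"),
    "excess_weight_loss": (None, None, "excess_weight_loss"),
    "body_fat": (None, None, "high_fat"),
    "ldl": (None, None, "high_ldl"),
    "bmm_group": (None, None, "high_bmm"),
}


@dataclass
class StudyConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    roc_criterion: str | float = "youden"
    cox_covariates: tuple = DEFAULT_COX_COVARIATES
    origins: tuple = ("onset", "admission")
    roc_origin: str = "onset"
    roc_weighting: str = "km"
    zero_duration_floor: float = 0.5
    min_age: float = 49.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for o in self.origins:
            if o not in ("onset", "admission"):
                raise ValueError(f"unknown origin {o!r}")

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        d = json.loads(text)
        if "thresholds" in d:
            d["thresholds"] = Thresholds.from_dict(d["thresholds"])
        if "cox_covariates" in d:
            d["cox_covariates"] = tuple(d["cox_covariates"])
        if "origins" in d:
            d["origins"] = tuple(d["origins"])
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    profiles: pd.DataFrame
    exclusions: pd.DataFrame
    four_cell_counts: dict
    comparisons: dict              # name -> comparison DataFrame
    km_curves: pd.DataFrame        # tidy: stratification, origin, group, time, ...
    logrank: dict                  # (stratification, origin) key -> result dict
    roc: dict                      # curve summary + cutoff choices (or skip note)
    cox: dict                      # origin -> CoxFit.to_dict()
    metadata: dict
    warnings: list

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(out / "cohort_augmented.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        for name, tab in self.comparisons.items():
            tab.to_csv(out / f"comparison_{name}.csv")
        comp_json = {name: json.loads(tab.reset_index().to_json(orient="records"))
                     for name, tab in self.comparisons.items()}
        (out / "comparisons.json").write_text(json.dumps(comp_json, indent=2))
        self.km_curves.to_csv(out / "km_curves.csv", index=False)
        (out / "logrank.json").write_text(json.dumps(self.logrank, indent=2))
        (out / "roc.json").write_text(json.dumps(
            {k: v for k, v in self.roc.items() if k != "curve"}, indent=2))
        if isinstance(self.roc.get("curve"), pd.DataFrame):
            self.roc["curve"].to_csv(out / "roc_curve.csv", index=False)
        (out / "cox.json").write_text(json.dumps(self.cox, indent=2))
        (out / "four_cell_counts.json").write_text(
            json.dumps(self.four_cell_counts, indent=2))
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2))
        (out / "run_log.txt").write_text("\n".join(self.warnings) + "\n")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (missing = empty cell, sex M/F,
    booleans 0/1); raises with a per-column report on schema violations."""
    df = pd.read_csv(path)
    problems = [f"missing required column {c!r}"
                for c in _REQUIRED_COLUMNS if c not in df.columns]
    if not problems:
        if df["height"].le(0).any():
            problems.append("non-positive heights: rows "
                            f"{df.index[df['height'] <= 0].tolist()}")
        if "sex" in df.columns:
            bad = ~df["sex"].dropna().isin(["M", "F"])
            if bad.any():
                problems.append(f"sex values outside {{M, F}}: "
                                f"{df['sex'].dropna()[bad].unique().tolist()}")
        fu = df["followup_months_from_onset"]
        if "months_since_onset" in df.columns:
            short = fu < df["months_since_onset"]
            if short.fillna(False).any():
                problems.append("follow-up shorter than onset-to-admission: rows "
                                f"{df.index[short.fillna(False)].tolist()}")
    if problems:
        raise ValueError("cohort CSV validation failed:\n  " + "\n  ".join(problems))
    return df


def exclusion_filter(records: pd.DataFrame, *, min_age: float = 49.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply enrolment exclusions; returns (kept, excluded-with-reasons).

    Excludes subjects younger than ``min_age`` (strictly) and, when
    pre-admission intervention columns are present, prior ventilation
    (``prior_nppv``) or gastrostomy (``prior_peg``). Records lacking those
    columns are kept.
    """
    reasons = []
    for idx, row in records.iterrows():
        why = []
        age = row.get("age")
        if pd.notna(age) and age < min_age:
            why.append(f"age < {min_age:g}")
        if bool(row.get("prior_nppv", 0) or 0) or bool(row.get("prior_ventilation", 0) or 0):
            why.append("mechanical ventilation before admission")
        if bool(row.get("prior_peg", 0) or 0):
            why.append("PEG before admission")
        reasons.append("; ".join(why))
    reasons = pd.Series(reasons, index=records.index)
    excluded = records.loc[reasons != ""].copy()
    excluded["exclusion_reason"] = reasons[reasons != ""]
    return records.loc[reasons == ""].copy(), excluded


def _numeric_view(profiles: pd.DataFrame) -> pd.DataFrame:
    """Comparison-ready copy: flags as floats, sex as an indicator."""
    df = profiles.copy()
    df["sex_female"] = df["sex"].map({"F": 1.0, "M": 0.0})
    for c in FLAG_COLUMNS + ["bulbar_onset", "peg", "nppv", "event"]:
        if c in df.columns:
            df[c] = df[c].astype("float64")
    return df


def _km_suite(profiles: pd.DataFrame, num: pd.DataFrame, origins,
              zero_floor: float, warnings_log: list):
    curves = []
    logrank_out = {}
    for origin in origins:
        surv = survival_from(profiles, origin, zero_floor=zero_floor)
        for name, (subset_flag, subset_val, group_flag) in KM_STRATIFICATIONS.items():
            mask = num[group_flag].notna()
            if subset_flag is not None:
                mask &= num[subset_flag] == float(subset_val)
            sub = num.loc[mask]
            key = f"{name}/{origin}"
            if sub.empty:
                warnings_log.append(f"WARNING {key}: empty stratum, skipped")
                continue
            groups = sorted(sub[group_flag].unique())
            if len(groups) < 2:
                warnings_log.append(f"WARNING {key}: single-group stratum, skipped")
                continue
            times, events = [], []
            for gval in groups:
                rows = sub.index[sub[group_flag] == gval]
                times.append(surv.loc[rows, "time"].to_numpy())
                events.append(surv.loc[rows, "event"].to_numpy())
                curve = km_estimate(times[-1], events[-1])
                cf = curve.to_frame()
                cf.insert(0, "group", f"{group_flag}={bool(gval)}")
                cf.insert(0, "origin", origin)
                cf.insert(0, "stratification", name)
                curves.append(cf)
            try:
                lr = logrank_test(times, events)
                logrank_out[key] = {"statistic": lr.statistic, "df": lr.df,
                                    "p": lr.p,
                                    "n": [int(t.size) for t in times]}
            except ValueError as e:
                warnings_log.append(f"WARNING {key}: log-rank skipped ({e})")
    km = (pd.concat(curves, ignore_index=True) if curves
          else pd.DataFrame(columns=["stratification", "origin", "group",
                                     "time", "survival", "at_risk", "events"]))
    return km, logrank_out


def run_study(cohort: pd.DataFrame, config: StudyConfig | None = None) -> StudyResult:
    """Execute the full analysis on a validated cohort table."""
    cfg = config or StudyConfig()
    t = cfg.thresholds
    warnings_log: list[str] = []

    kept, excluded = exclusion_filter(cohort, min_age=cfg.min_age)
    if len(excluded):
        warnings_log.append(f"INFO excluded {len(excluded)} subjects at enrolment")

    profiles = MetabolicProfiler(thresholds=t).fit(kept).transform(kept)
    num = _numeric_view(profiles)

    # four-cell nutrition x metabolism partition (complete BMI and mREE/LSTM)
    complete = num["malnourished"].notna() & num["hypermetabolic"].notna()
    cells = {}
    for mal in (False, True):
        for hyper in (False, True):
            key = (f"{'malnourished' if mal else 'normal_weight'}/"
                   f"{'hypermetabolic' if hyper else 'normometabolic'}")
            cells[key] = int(((num["malnourished"] == float(mal))
                              & (num["hypermetabolic"] == float(hyper))).sum())
    four_cell = {"cells": cells, "n_complete": int(complete.sum())}

    comparisons = {}
    for name, subset_val in (("normal_weight", 0.0), ("malnutrition", 1.0)):
        sub = num[num["malnourished"] == subset_val]
        if sub["hypermetabolic"].nunique() == 2:
            comparisons[f"metabolism_within_{name}"] = compare_groups(
                sub, "hypermetabolic", TABLE1_VARIABLES)
        else:
            warnings_log.append(f"WARNING comparison metabolism_within_{name}: "
                                "degenerate grouping, skipped")
    if num["high_bmm"].nunique() == 2:
        comparisons["bmm_groups"] = compare_groups(
            num[num["high_bmm"].notna()], "high_bmm", TABLE2_VARIABLES)
    else:
        warnings_log.append("WARNING comparison bmm_groups: degenerate grouping, skipped")

    km_curves, logrank_out = _km_suite(profiles, num, cfg.origins,
                                       cfg.zero_duration_floor, warnings_log)

    # time-dependent ROC on the BMM index
    roc: dict = {}
    roc_rows = num["bmm"].notna()
    surv = survival_from(profiles.loc[roc_rows], cfg.roc_origin,
                         zero_floor=cfg.zero_duration_floor)
    try:
        curve = td_roc(num.loc[roc_rows, "bmm"].to_numpy(),
                       surv["time"].to_numpy(), surv["event"].to_numpy(),
                       t.roc_horizon, weighting=cfg.roc_weighting)
        chosen = select_cutoff(curve, cfg.roc_criterion)
        preset = select_cutoff(curve, t.bmm_cut)
        roc = {
            "horizon": t.roc_horizon,
            "origin": cfg.roc_origin,
            "n": int(roc_rows.sum()),
            "auc": curve.auc,
            "selected": asdict_choice(chosen),
            "preset_at_bmm_cut": asdict_choice(preset),
            "curve": pd.DataFrame({
                "cutoff": curve.cutoffs,
                "sensitivity": curve.sensitivity,
                "one_minus_specificity": curve.one_minus_specificity,
            }),
        }
    except ValueError as e:
        warnings_log.append(f"WARNING tdROC skipped ({e})")
        roc = {"skipped": str(e)}

    # Cox models, listwise deletion within each origin's model
    cox_out = {}
    for origin in cfg.origins:
        covs = list(cfg.cox_covariates)
        missing_cols = [c for c in covs if c not in num.columns]
        if missing_cols:
            raise ValueError(f"Cox covariates not in augmented schema: {missing_cols}")
        X = num[covs].astype(float)
        complete_rows = X.notna().all(axis=1)
        surv = survival_from(profiles.loc[complete_rows], origin,
                             zero_floor=cfg.zero_duration_floor)
        if not surv["event"].any():
            warnings_log.append(f"WARNING cox/{origin}: no events, skipped")
            continue
        fit = cox_fit(X.loc[complete_rows], surv["time"].to_numpy(),
                      surv["event"].to_numpy(), covariates=covs)
        d = fit.to_dict()
        d["_model"]["n"] = int(complete_rows.sum())
        d["_model"]["events"] = int(surv["event"].sum())
        cox_out[origin] = d

    metadata = {
        "config_hash": cfg.config_hash(),
        "thresholds": t.to_dict(),
        "n_input": int(len(cohort)),
        "n_analyzed": int(len(kept)),
        "n_excluded": int(len(excluded)),
    }
    return StudyResult(profiles=profiles, exclusions=excluded,
                       four_cell_counts=four_cell, comparisons=comparisons,
                       km_curves=km_curves, logrank=logrank_out, roc=roc,
                       cox=cox_out, metadata=metadata, warnings=warnings_log)


def asdict_choice(choice) -> dict:
    return {"cutoff": float(choice.cutoff),
            "sensitivity": float(choice.sensitivity),
            "specificity": float(choice.specificity),
            "criterion": str(choice.criterion)}
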