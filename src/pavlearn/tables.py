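"""Readers, writers, schema validation, configuration and clinical utilities.

All tables are comma-separated UTF-8 with a mandatory header, '.' decimal
separator and empty fields for missing values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .task import CONDITION_NAMES, GO, MISSED, NOGO

TRIAL_COLUMNS = ["subject_id", "administration", "trial_index", "condition", "action", "outcome", "rt"]
GOAL_COLUMNS = ["subject_id", "day", "activity_id", "category", "R_pre", "P_pre", "r", "p", "R_post1", "P_post1"]
SYMPTOM_COLUMNS = ["subject_id", "week", "ids_total", "item19", "item21"]


def write_trials(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_goal(df: pd.DataFrame, path) -> None:
    df[GOAL_COLUMNS].to_csv(path, index=False)


def read_goal(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_symptoms(df: pd.DataFrame, path) -> None:
    df[SYMPTOM_COLUMNS].to_csv(path, index=False)


def read_symptoms(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class Violation:
    table: str
    row: int | None
    message: str

    def __str__(self) -> str:
        loc = f" (row {self.row})" if self.row is not None else ""
        return f"{self.table}{loc}: {self.message}"


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, table: str, row, message: str) -> None:
        self.violations.append(Violation(table=table, row=row, message=message))

    def __str__(self) -> str:
        if self.ok:
            return "all tables valid"
        return "\n".join(str(v) for v in self.violations)


def _check_columns(df, required, table, report) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        report.add(table, None, f"missing columns: {missing}")
        return False
    return True


def validate_trials(df: pd.DataFrame, report: ValidationReport | None = None) -> ValidationReport:
    report = report if report is not None else ValidationReport()
    if not _check_columns(df, TRIAL_COLUMNS[:-1], "trials", report):
        return report
    for i, row in df.iterrows():
        if row["condition"] not in CONDITION_NAMES:
            report.add("trials", i, f"unknown condition {row['condition']!r}")
        if row["action"] not in (GO, NOGO, MISSED):
            report.add("trials", i, f"unknown action {row['action']!r}")
        if row["outcome"] not in (-1, 0, 1):
            report.add("trials", i, f"outcome {row['outcome']!r} not in {{-1, 0, 1}}")
        if not 1 <= row["administration"] <= 5:
            report.add("trials", i, f"administration {row['administration']} outside 1..5")
    for (sid, admin), g in df.groupby(["subject_id", "administration"]):
        tidx = g["trial_index"].to_numpy()
        if np.any(np.diff(tidx) <= 0):
            report.add("trials", int(g.index[np.argmax(np.diff(tidx) <= 0) + 1]),
                       f"trial_index not increasing for subject {sid}, administration {admin}")
        if len(np.unique(tidx)) != len(tidx):
            report.add("trials", None, f"duplicate trial_index for subject {sid}, administration {admin}")
    return report


def validate_goal(df: pd.DataFrame, scale: tuple = (0, 10), report: ValidationReport | None = None) -> ValidationReport:
    report = report if report is not None else ValidationReport()
    if not _check_columns(df, GOAL_COLUMNS, "goal", report):
        return report
    lo, hi = scale
    rating_cols = ["R_pre", "P_pre", "r", "p", "R_post1", "P_post1"]
    for i, row in df.iterrows():
        if not 1 <= row["day"] <= 56:
            report.add("goal", i, f"day {row['day']} outside 1..56")
        for c in rating_cols:
            v = row[c]
            if pd.notna(v) and not lo <= v <= hi:
                report.add("goal", i, f"{c}={v} outside rating scale [{lo}, {hi}]")
    dup = df.duplicated(subset=["subject_id", "day", "activity_id"], keep=False)
    for i in df.index[dup]:
        report.add("goal", int(i), "duplicate (subject, day, activity)")
    return report


def validate_symptoms(df: pd.DataFrame, report: ValidationReport | None = None) -> ValidationReport:
    report = report if report is not None else ValidationReport()
    if not _check_columns(df, SYMPTOM_COLUMNS, "symptoms", report):
        return report
    for i, row in df.iterrows():
        if pd.notna(row["ids_total"]) and not 0 <= row["ids_total"] <= 84:
            report.add("symptoms", i, f"ids_total {row['ids_total']} outside 0..84")
        for item in ("item19", "item21"):
            if pd.notna(row[item]) and not 0 <= row[item] <= 3:
                report.add("symptoms", i, f"{item} {row[item]} outside 0..3")
    for sid, g in df.groupby("subject_id"):
        if np.any(np.diff(g["week"].to_numpy()) <= 0):
            report.add("symptoms", None, f"weeks not strictly increasing for subject {sid}")
    return report


def validate_tables(
    trials_path=None, goal_path=None, symptoms_path=None, scale: tuple = (0, 10)
) -> ValidationReport:
    """Schema, range and ordering checks over any subset of the three tables."""
    report = ValidationReport()
    if trials_path is not None:
        validate_trials(read_trials(trials_path), report)
    if goal_path is not None:
        validate_goal(read_goal(goal_path), scale=scale, report=report)
    if symptoms_path is not None:
        validate_symptoms(read_symptoms(symptoms_path), report)
    return report


def rate_from_counts(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, e.g. (18, 80) -> 22.5."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 1)


def responder_flags(
    series: pd.DataFrame,
    baseline_week: int = 0,
    final_week: int = 9,
) -> pd.DataFrame:
    """Treatment-response flags per subject from weekly total scores.

    response25 / response50: >= 25% / 50% reduction from baseline to the
    final week; remission: final score strictly below 14.  Subjects missing
    either endpoint get NA flags.
    """
    rows = []
    for sid, g in series.groupby("subject_id"):
        base = g.loc[g["week"] == baseline_week, "ids_total"]
        final = g.loc[g["week"] == final_week, "ids_total"]
        if base.empty or final.empty or base.isna().all() or final.isna().all():
            rows.append({"subject_id": sid, "response25": pd.NA, "response50": pd.NA, "remission": pd.NA})
            continue
        b, f = float(base.iloc[0]), float(final.iloc[0])
        reduction = (b - f) / b if b > 0 else np.nan
        rows.append(
            {
                "subject_id": sid,
                "response25": bool(reduction >= 0.25),
                "response50": bool(reduction >= 0.50),
                "remission": bool(f < 14),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Resolved run configuration; fully serializable and hashable for logging."""

    seed: int = 0
    n_per_condition: int = 60
    dominant_prob: float = 0.8
    outcome_rule_variant: str = "conventional"
    models: list = field(default_factory=lambda: ["RW+noise+bias+2Pav", "RW+noise+bias+2Pav+session"])
    em_tol: float = 1e-3
    em_max_iter: int = 50
    n_restarts: int = 10
    ibic_samples: int = 2000
    rating_scale: list = field(default_factory=lambda: [0, 10])
    t3_week: int = 4
    t7_week: int = 7

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
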