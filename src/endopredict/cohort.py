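"""Cohort data model: codebook-driven tabular I/O, outcome dichotomization and filters.

A :class:`CohortTable` is one row per woman, carrying a baseline and a 6-month
follow-up score for a single outcome (pain VAS 0-10 or a 0-100 quality-of-life
barometer) plus a set of candidate predictors typed by a :class:`Codebook`.

The outcome is dichotomized into an "improved" indicator: for VAS pain scores a
relative reduction of at least 30% from baseline counts as improved; for
quality of life an absolute gain of at least 10 points (out of 100) does.
Records with baseline VAS of exactly zero have an undefined relative reduction
and are excluded from that outcome's analysis set, with the count logged.

Missing-data policy is deliberately simple: candidate predictors missing in
half or more of records are dropped from model building, and development then
proceeds on complete cases only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

VAS_RANGE = (0.0, 10.0)
QOL_RANGE = (0.0, 100.0)
ELIGIBLE_AGE = (16.0, 65.0)

MISSINGNESS_EXCLUSION_FRACTION = 0.50


@dataclass(frozen=True)
class OutcomeRule:
    """Dichotomization rule for a pain or quality-of-life outcome.

    ``vas_reduction``: improved iff (baseline - followup)/baseline >= vas_threshold.
    ``qol_gain``:      improved iff followup - baseline >= qol_threshold points.
    Both comparisons are inclusive ("a minimum of" the stated change improves).
    """

    kind: str = "vas_reduction"
    vas_threshold: float = 0.30
    qol_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("vas_reduction", "qol_gain"):
            raise ValueError(f"unknown outcome rule kind: {self.kind}")
        if not (0.0 < self.vas_threshold < 1.0):
            raise ValueError("vas_threshold must lie in (0, 1)")
        if self.qol_threshold <= 0:
            raise ValueError("qol_threshold must be positive")


@dataclass(frozen=True)
class PredictorSpec:
    """Codebook entry for one predictor column."""

    type: str  # continuous | binary | categorical
    levels: tuple[str, ...] | None = None
    reference: str | None = None
    mandatory: bool = False

    def __post_init__(self) -> None:
        if self.type not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown predictor type: {self.type}")
        if self.type == "categorical":
            if not self.levels:
                raise ValueError("categorical predictor needs levels")
            if self.reference is None or self.reference not in self.levels:
                raise ValueError("categorical predictor needs exactly one reference level from its levels")


@dataclass(frozen=True)
class Codebook:
    """Column roles and types for one single-outcome cohort table.

    One table carries one outcome at one fixed follow-up horizon (6 months);
    the baseline score column is mandatory in any model for this outcome.
    """

    outcome: str
    scale: str  # "vas" | "qol"
    predictors: Mapping[str, PredictorSpec]
    id_column: str = "id"
    baseline_column: str = "baseline_score"
    followup_column: str = "followup_score"
    age_column: str | None = "age"

    def __post_init__(self) -> None:
        if self.scale not in ("vas", "qol"):
            raise ValueError(f"scale must be 'vas' or 'qol', got {self.scale!r}")

    @property
    def score_range(self) -> tuple[float, float]:
        return VAS_RANGE if self.scale == "vas" else QOL_RANGE

    def default_rule(self) -> OutcomeRule:
        return OutcomeRule(kind="vas_reduction" if self.scale == "vas" else "qol_gain")

    def to_dict(self) -> dict:
        preds = {}
        for name, p in self.predictors.items():
            d: dict = {"type": p.type}
            if p.levels:
                d["levels"] = list(p.levels)
                d["reference"] = p.reference
            if p.mandatory:
                d["mandatory"] = True
            preds[name] = d
        return {
            "outcome": self.outcome,
            "scale": self.scale,
            "id_column": self.id_column,
            "baseline_column": self.baseline_column,
            "followup_column": self.followup_column,
            "age_column": self.age_column,
            "predictors": preds,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        preds = {
            name: PredictorSpec(
                type=spec["type"],
                levels=tuple(spec["levels"]) if spec.get("levels") else None,
                reference=spec.get("reference"),
                mandatory=bool(spec.get("mandatory", False)),
            )
            for name, spec in d["predictors"].items()
        }
        return cls(
            outcome=d["outcome"],
            scale=d["scale"],
            predictors=preds,
            id_column=d.get("id_column", "id"),
            baseline_column=d.get("baseline_column", "baseline_score"),
            followup_column=d.get("followup_column", "followup_score"),
            age_column=d.get("age_column", "age"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class CohortTable:
    """A cohort: a DataFrame of patient records plus its codebook."""

    df: pd.DataFrame
    codebook: Codebook

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cb = self.codebook
        needed = [cb.id_column, cb.baseline_column, cb.followup_column, *cb.predictors]
        missing = [c for c in needed if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort is missing codebook columns: {missing}")
        ids = self.df[cb.id_column]
        if ids.duplicated().any():
            raise ValueError("duplicated record identifiers")
        lo, hi = cb.score_range
        for col in (cb.baseline_column, cb.followup_column):
            vals = pd.to_numeric(self.df[col], errors="coerce")
            observed = vals.dropna()
            if ((observed < lo) | (observed > hi)).any():
                bad = observed[(observed < lo) | (observed > hi)].iloc[0]
                raise ValueError(f"{col} value {bad} outside [{lo}, {hi}] for scale {cb.scale!r}")
        for name, spec in cb.predictors.items():
            if spec.type == "categorical":
                observed = self.df[name].dropna()
                unknown = set(map(str, observed.unique())) - set(spec.levels)
                if unknown:
                    raise ValueError(f"predictor {name!r} has levels outside the codebook: {sorted(unknown)}")
            elif spec.type == "binary":
                observed = pd.to_numeric(self.df[name], errors="coerce").dropna()
                if not observed.isin([0, 1]).all():
                    raise ValueError(f"binary predictor {name!r} has values outside {{0, 1}}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.codebook)

    # ---- persistence -------------------------------------------------

    def save(self, csv_path: str | Path, codebook_path: str | Path | None = None) -> None:
        """Write the cohort as CSV (empty fields for missing) + YAML codebook."""
        self.df.to_csv(csv_path, index=False)
        if codebook_path is not None:
            self.codebook.save(codebook_path)

    @classmethod
    def load(
        cls,
        csv_path: str | Path,
        codebook: Codebook | str | Path,
        na_values: str | list[str] | None = None,
    ) -> "CohortTable":
        if not isinstance(codebook, Codebook):
            codebook = Codebook.load(codebook)
        df = pd.read_csv(csv_path, na_values=na_values)
        for name, spec in codebook.predictors.items():
            if spec.type == "categorical" and name in df.columns:
                df[name] = df[name].astype("string").astype(object)
        return cls(df, codebook)


# ---------------------------------------------------------------------------
# dichotomization


def dichotomize_vas(baseline: float, followup: float, rule: OutcomeRule | None = None) -> int:
    """1 iff the relative VAS reduction (baseline - followup)/baseline meets the threshold.

    A reduction of exactly the threshold (30% by default) counts as improved.
    Baseline of zero has an undefined relative reduction and is a ValueError
    here; cohort-level dichotomization excludes such records with a logged count.
    """
    rule = rule or OutcomeRule(kind="vas_reduction")
    for name, v in (("baseline", baseline), ("followup", followup)):
        if not (VAS_RANGE[0] <= v <= VAS_RANGE[1]):
            raise ValueError(f"VAS {name} score {v} outside [0, 10]")
    if baseline == 0:
        raise ValueError("relative reduction undefined for baseline VAS of 0")
    return int((baseline - followup) / baseline >= rule.vas_threshold)


def dichotomize_qol(baseline: float, followup: float, rule: OutcomeRule | None = None) -> int:
    """1 iff the quality-of-life gain followup - baseline is at least the threshold (10 points)."""
    rule = rule or OutcomeRule(kind="qol_gain")
    for name, v in (("baseline", baseline), ("followup", followup)):
        if not (QOL_RANGE[0] <= v <= QOL_RANGE[1]):
            raise ValueError(f"QoL {name} score {v} outside [0, 100]")
    return int(followup - baseline >= rule.qol_threshold)


def outcome_indicator(
    table: CohortTable, rule: OutcomeRule | None = None
) -> tuple[pd.Series, dict]:
    """Vectorized improvement indicator for a whole table.

    Returns the 0/1 indicator (NaN where undefined) and a log with counts of
    records excluded for undefined relative reduction (baseline VAS = 0) or
    missing scores.
    """
    cb = table.codebook
    rule = rule or cb.default_rule()
    b = pd.to_numeric(table.df[cb.baseline_column], errors="coerce")
    f = pd.to_numeric(table.df[cb.followup_column], errors="coerce")
    missing = b.isna() | f.isna()
    if cb.scale == "vas":
        if rule.kind != "vas_reduction":
            raise ValueError("VAS-scaled table requires a vas_reduction rule")
        zero_base = (b == 0) & ~missing
        defined = ~missing & ~zero_base
        y = pd.Series(np.nan, index=table.df.index)
        y[defined] = ((b[defined] - f[defined]) / b[defined] >= rule.vas_threshold).astype(float)
        log = {
            "rule": "vas_reduction",
            "threshold": rule.vas_threshold,
            "n": int(len(table.df)),
            "missing_scores": int(missing.sum()),
            "undefined_relative_reduction": int(zero_base.sum()),
        }
    else:
        if rule.kind != "qol_gain":
            raise ValueError("QoL-scaled table requires a qol_gain rule")
        defined = ~missing
        y = pd.Series(np.nan, index=table.df.index)
        y[defined] = (f[defined] - b[defined] >= rule.qol_threshold).astype(float)
        log = {
            "rule": "qol_gain",
            "threshold": rule.qol_threshold,
            "n": int(len(table.df)),
            "missing_scores": int(missing.sum()),
            "undefined_relative_reduction": 0,
        }
    log["defined"] = int(defined.sum())
    log["events"] = int(np.nansum(y.values))
    return y, log


# ---------------------------------------------------------------------------
# eligibility and missing-data filters


def filter_eligibility(
    table: CohortTable,
    age_range: tuple[float, float] = ELIGIBLE_AGE,
    endometriosis_column: str | None = None,
) -> tuple[CohortTable, dict]:
    """Apply the eligibility filter: age within range (16-65 years) and, when a
    flag column is named, a confirmed/suspected endometriosis indicator of 1.

    Records with missing age are retained (age missingness is handled by the
    complete-case step if age enters a model). Returns the filtered table and
    a log of counts per exclusion reason.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    log: dict = {"n_in": int(len(df))}
    age_col = table.codebook.age_column
    if age_col is not None and age_col in df.columns:
        age = pd.to_numeric(df[age_col], errors="coerce")
        bad_age = age.notna() & ((age < age_range[0]) | (age > age_range[1]))
        log["excluded_age"] = int(bad_age.sum())
        keep &= ~bad_age
    if endometriosis_column is not None:
        flag = pd.to_numeric(df[endometriosis_column], errors="coerce")
        bad = flag.notna() & (flag != 1)
        log["excluded_no_endometriosis"] = int(bad.sum())
        keep &= ~bad
    out = CohortTable(df[keep].reset_index(drop=True), table.codebook)
    log["n_out"] = int(len(out.df))
    return out, log


def screen_missingness(
    table: CohortTable, candidates: Iterable[str]
) -> tuple[list[str], dict]:
    """Drop candidate predictors missing in >= 50% of records.

    Returns the retained predictor names (input order preserved) and a log of
    per-predictor missing fractions with the exclusion decision.
    """
    candidates = list(candidates)
    if len(table.df) == 0:
        raise ValueError("cannot screen missingness on an empty table")
    unknown = [c for c in candidates if c not in table.codebook.predictors]
    if unknown:
        raise KeyError(f"candidates not in codebook: {unknown}")
    retained: list[str] = []
    log = {"n": int(len(table.df)), "threshold": MISSINGNESS_EXCLUSION_FRACTION, "predictors": {}}
    for name in candidates:
        frac = float(table.df[name].isna().mean())
        excluded = frac >= MISSINGNESS_EXCLUSION_FRACTION
        log["predictors"][name] = {"missing_fraction": frac, "excluded": bool(excluded)}
        if not excluded:
            retained.append(name)
    return retained, log


def complete_case(
    table: CohortTable, predictors: Iterable[str]
) -> tuple[CohortTable, dict]:
    """Keep exactly the rows with observed baseline score, follow-up score and
    every listed predictor. Returns the filtered table and retained/dropped counts.
    """
    cb = table.codebook
    predictors = list(predictors)
    unknown = [c for c in predictors if c not in cb.predictors]
    if unknown:
        raise KeyError(f"predictors not in codebook: {unknown}")
    cols = [cb.baseline_column, cb.followup_column, *predictors]
    keep = table.df[cols].notna().all(axis=1)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("complete-case filter left zero rows")
    out = CohortTable(table.df[keep].reset_index(drop=True), cb)
    log = {"n_in": int(len(table.df)), "retained": n_kept, "dropped": int(len(table.df) - n_kept)}
    return out, log


def save_filter_log(log: dict, path: str | Path) -> None:
    """Write a filter/exclusion log as JSON."""
    Path(path).write_text(json.dumps(log, indent=2, sort_keys=True))
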