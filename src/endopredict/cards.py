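"""Frozen prediction-model cards: terms, coefficients, transforms, provenance.

A :class:`ModelCard` is the exchange format for a developed logistic model: its
terms (continuous predictors with their fractional-polynomial transforms,
binary flags, categorical dummies), log-odds coefficients, intercept, any
uniform shrinkage applied, and a performance block. Cards are JSON on disk and
can score a new cohort without refitting, which is exactly what external
validation requires.

Eight published models for pain/quality-of-life improvement after laparoscopic
endometriosis surgery ship with the package (see :func:`list_shipped_cards`):
three developed on the predictor set available for external validation
(dysmenorrhoea, dyspareunia, non-cyclical pelvic pain) and five developed on
the full candidate list (those three plus dyschezia and quality of life).
Coefficients are the natural logs of the published odds ratios; per-field
rounding provenance is recorded in each card's notes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .transforms import FPTransform

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ContinuousTerm:
    name: str
    transform: FPTransform
    coef: float
    se: float | None = None

    @property
    def column_names(self) -> list[str]:
        return [self.name]

    @property
    def coefs(self) -> list[float]:
        return [self.coef]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        return self.transform(df[self.name].to_numpy(dtype=float))[:, None]


@dataclass(frozen=True)
class BinaryTerm:
    name: str
    coef: float
    se: float | None = None

    @property
    def column_names(self) -> list[str]:
        return [self.name]

    @property
    def coefs(self) -> list[float]:
        return [self.coef]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        vals = df[self.name].to_numpy(dtype=float)
        return vals[:, None]


@dataclass(frozen=True)
class CategoricalTerm:
    """Dummy encoding of a categorical predictor against its reference level."""

    name: str
    reference: str
    levels: tuple[str, ...]  # non-reference levels, in display order
    coefs_by_level: tuple[float, ...]
    ses_by_level: tuple[float | None, ...] | None = None

    @property
    def column_names(self) -> list[str]:
        return [f"{self.name}[{lvl}]" for lvl in self.levels]

    @property
    def coefs(self) -> list[float]:
        return list(self.coefs_by_level)

    def design(self, df: pd.DataFrame) -> np.ndarray:
        vals = df[self.name].astype(str)
        known = set(self.levels) | {self.reference}
        unseen = set(vals.unique()) - known
        if unseen:
            raise ValueError(
                f"predictor {self.name!r} has levels unseen in the card encoding: {sorted(unseen)}"
            )
        return np.column_stack([(vals == lvl).to_numpy(dtype=float) for lvl in self.levels])


Term = ContinuousTerm | BinaryTerm | CategoricalTerm


def design_matrix(terms: Sequence[Term], df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Stack term design columns (no intercept column) with their names."""
    missing = [t.name for t in terms if t.name not in df.columns]
    if missing:
        raise KeyError(f"cohort is missing predictor columns: {missing}")
    blocks, names = [], []
    for t in terms:
        blocks.append(t.design(df))
        names.extend(t.column_names)
    if not blocks:
        return np.empty((len(df), 0)), []
    return np.column_stack(blocks), names


@dataclass
class ModelCard:
    """A frozen logistic prediction model for one improvement outcome."""

    name: str
    outcome: str
    scale: str  # "vas" | "qol"
    terms: list[Term]
    intercept: float
    intercept_se: float | None = None
    n: int | None = None
    events: int | None = None
    shrinkage: float | None = None
    performance: dict = field(default_factory=dict)
    odds_ratios: dict = field(default_factory=dict)  # printed ORs/CIs, per term label
    notes: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    # ---- scoring -----------------------------------------------------

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        """Log-odds of improvement for each row, using the stored transforms,
        centering constants and coefficients; the card is never refitted."""
        X, _ = design_matrix(self.terms, df)
        coefs = np.concatenate([np.asarray(t.coefs, dtype=float) for t in self.terms]) if self.terms else np.empty(0)
        return self.intercept + X @ coefs

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted probability of improvement; strictly inside (0, 1)."""
        p = expit(self.linear_predictor(df))
        tiny = np.finfo(float).tiny
        return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)

    @property
    def predictor_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def event_percent(self) -> float:
        """Event percentage recomputed from the stored counts (never stored itself)."""
        if self.n is None or self.events is None:
            raise ValueError("card has no development counts")
        return 100.0 * self.events / self.n

    # ---- (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        terms = []
        for t in self.terms:
            if isinstance(t, ContinuousTerm):
                terms.append(
                    {
                        "name": t.name,
                        "kind": "continuous",
                        "transform": {
                            "shift": t.transform.shift,
                            "scale": t.transform.scale,
                            "power": t.transform.power,
                            "center": t.transform.center,
                        },
                        "coef": t.coef,
                        "se": t.se,
                    }
                )
            elif isinstance(t, BinaryTerm):
                terms.append({"name": t.name, "kind": "binary", "coef": t.coef, "se": t.se})
            else:
                terms.append(
                    {
                        "name": t.name,
                        "kind": "categorical",
                        "reference": t.reference,
                        "levels": [
                            {
                                "level": lvl,
                                "coef": c,
                                "se": (t.ses_by_level[i] if t.ses_by_level else None),
                            }
                            for i, (lvl, c) in enumerate(zip(t.levels, t.coefs_by_level))
                        ],
                    }
                )
        return {
            "schema_version": self.schema_version,
            "name": self.name,
            "outcome": self.outcome,
            "scale": self.scale,
            "n": self.n,
            "events": self.events,
            "intercept": {"value": self.intercept, "se": self.intercept_se},
            "terms": terms,
            "shrinkage": self.shrinkage,
            "performance": self.performance,
            "odds_ratios": self.odds_ratios,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelCard":
        terms: list[Term] = []
        odds_ratios = dict(d.get("odds_ratios", {}))
        for td in d["terms"]:
            kind = td["kind"]
            # harvest printed odds ratios/CIs (when present) for reporting
            if kind in ("continuous", "binary") and td.get("or") is not None:
                odds_ratios[td["name"]] = {"or": td["or"], "ci": td.get("ci")}
            elif kind == "categorical":
                for lv in td.get("levels", []):
                    if lv.get("or") is not None:
                        odds_ratios[f"{td['name']}[{lv['level']}]"] = {"or": lv["or"], "ci": lv.get("ci")}
            if kind == "continuous":
                tr = td.get("transform") or {}
                coef = td["coef"] if td.get("coef") is not None else math.log(td["or"])
                terms.append(
                    ContinuousTerm(
                        td["name"],
                        FPTransform(
                            shift=tr.get("shift", 0.0),
                            scale=tr.get("scale", 1.0),
                            power=tr.get("power", 1.0),
                            center=tr.get("center", 0.0),
                        ),
                        coef=float(coef),
                        se=td.get("se"),
                    )
                )
            elif kind == "binary":
                coef = td["coef"] if td.get("coef") is not None else math.log(td["or"])
                terms.append(BinaryTerm(td["name"], coef=float(coef), se=td.get("se")))
            elif kind == "categorical":
                levels, coefs, ses = [], [], []
                for lv in td["levels"]:
                    levels.append(lv["level"])
                    coefs.append(float(lv["coef"] if lv.get("coef") is not None else math.log(lv["or"])))
                    ses.append(lv.get("se"))
                terms.append(
                    CategoricalTerm(
                        td["name"], td["reference"], tuple(levels), tuple(coefs), tuple(ses)
                    )
                )
            else:
                raise ValueError(f"unknown term kind {kind!r}")
        icpt = d.get("intercept", {})
        if not isinstance(icpt, dict):
            icpt = {"value": icpt}
        return cls(
            name=d["name"],
            outcome=d["outcome"],
            scale=d["scale"],
            terms=terms,
            intercept=float(icpt["value"]),
            intercept_se=icpt.get("se"),
            n=d.get("n"),
            events=d.get("events"),
            shrinkage=d.get("shrinkage"),
            performance=d.get("performance", {}),
            odds_ratios=odds_ratios,
            notes=d.get("notes", {}),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelCard":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the card content, for never-mutated assertions."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# shipped published cards


def list_shipped_cards() -> list[str]:
    """Names of the model cards shipped with the package."""
    pkg = resources.files("endopredict") / "cards_data"
    return sorted(p.name.removesuffix(".json") for p in pkg.iterdir() if p.name.endswith(".json"))


def load_shipped_card(name: str) -> ModelCard:
    """Load one shipped published model card by name (see :func:`list_shipped_cards`)."""
    pkg = resources.files("endopredict") / "cards_data" / f"{name}.json"
    try:
        text = pkg.read_text()
    except FileNotFoundError as exc:
        raise KeyError(f"no shipped card named {name!r}; available: {list_shipped_cards()}") from exc
    return ModelCard.from_dict(json.loads(text))


def load_all_shipped_cards() -> dict[str, ModelCard]:
    return {name: load_shipped_card(name) for name in list_shipped_cards()}
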