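"""Decision-curve analysis: net benefit of a prediction-guided treatment rule.

At a threshold probability ``pt``, a patient is classified "treat" when the
predicted probability of improvement is at least ``pt``.  Net benefit trades
true against false positives at the exchange rate implied by the threshold:

    NB(pt) = TP/n - (FP/n) * pt / (1 - pt)

in units of true positives per patient.  The model's curve is compared with
the treat-all strategy (everyone classified treat, NB = phi - (1-phi)*pt/(1-pt)
for prevalence phi) and treat-none (identically zero).  The default grid spans
thresholds 0 to 0.80 in steps of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cards import ModelCard
from .cohort import complete_case, outcome_indicator

DEFAULT_GRID = np.round(np.arange(0.0, 0.80 + 1e-9, 0.01), 2)


@dataclass
class DecisionCurve:
    """Net benefit over a threshold grid for model, treat-all and treat-none."""

    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray
    n: int
    events: int

    @property
    def prevalence(self) -> float:
        return self.events / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit_model": self.net_benefit_model,
                "net_benefit_all": self.net_benefit_all,
                "net_benefit_none": self.net_benefit_none,
            }
        )


def net_benefit(predictions, outcomes, pt: float) -> float:
    """Net benefit of treating when prediction >= pt (inclusive classification)."""
    if not (0.0 <= pt < 1.0):
        raise ValueError("threshold probability must lie in [0, 1); the weight is undefined at 1")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(y)
    treat = p >= pt
    tp = float(np.sum(treat & (y == 1)))
    fp = float(np.sum(treat & (y == 0)))
    w = pt / (1.0 - pt)
    return tp / n - (fp / n) * w


def decision_curve(
    card_or_predictions,
    table_or_outcomes,
    grid: np.ndarray | None = None,
) -> DecisionCurve:
    """Evaluate net benefit over a threshold grid for model / treat-all / treat-none.

    Accepts either (ModelCard, CohortTable) — the card scores the table's
    complete cases — or raw (predictions, outcomes) arrays.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if isinstance(card_or_predictions, ModelCard):
        card, table = card_or_predictions, table_or_outcomes
        needed = [t.name for t in card.terms if t.name in table.codebook.predictors]
        cc, _ = complete_case(table, needed)
        y_all, _ = outcome_indicator(cc)
        keep = y_all.notna()
        df = cc.df[keep].reset_index(drop=True)
        y = y_all[keep].to_numpy(dtype=float)
        p = card.predict(df)
    else:
        p = np.asarray(card_or_predictions, dtype=float)
        y = np.asarray(table_or_outcomes, dtype=float)
    n = len(y)
    phi = float(y.mean())
    nb_model = np.array([net_benefit(p, y, pt) for pt in grid])
    nb_all = phi - (1.0 - phi) * grid / (1.0 - grid)
    nb_none = np.zeros_like(grid)
    return DecisionCurve(grid, nb_model, nb_all, nb_none, n=n, events=int(y.sum()))
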