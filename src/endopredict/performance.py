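"""Discrimination and calibration metrics for predicted probabilities.

* C-statistic: probability a randomly chosen improver gets a higher predicted
  risk than a randomly chosen non-improver (= area under the ROC curve),
  computed by the rank (Mann-Whitney) formulation with midranks for ties.
* Calibration slope: slope from a logistic refit of the outcome on the model's
  linear predictor (ideal 1; below 1 means predictions too extreme, i.e.
  overfitting).
* Calibration-in-the-large (CITL): intercept of that regression with the slope
  fixed at 1 via an offset (ideal 0; negative means systematic overprediction).
* Grouped calibration curve: equal-size risk groups (deciles by default) with
  mean predicted probability versus observed event fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit
from scipy.stats import rankdata

from ._logit import fit_logit


@dataclass
class CalibrationPoint:
    mean_predicted: float
    observed_fraction: float
    size: int


@dataclass
class PerformanceReport:
    """Discrimination + calibration summary for one (predictions, outcomes) pairing."""

    c_statistic: float
    calibration_slope: float
    citl: float
    n: int
    events: int
    calibration_curve: list[CalibrationPoint] = field(default_factory=list)
    degenerate_calibration: bool = False

    def to_dict(self) -> dict:
        return {
            "c_statistic": self.c_statistic,
            "calibration_slope": self.calibration_slope,
            "citl": self.citl,
            "n": self.n,
            "events": self.events,
            "calibration_curve": [
                {"mean_predicted": p.mean_predicted, "observed_fraction": p.observed_fraction, "size": p.size}
                for p in self.calibration_curve
            ],
        }


def _check_classes(y: np.ndarray) -> None:
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")


def c_statistic(predictions, outcomes) -> float:
    """Concordance probability with ties counted one half; equals AUROC.

    Invariant under any strictly increasing transform of the predictions, so
    probabilities and linear predictors give the same value.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    r = rankdata(p)  # midranks
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def calibration_slope(linear_predictors, outcomes) -> float:
    """Slope of a logistic regression of outcome on the linear predictor (free intercept)."""
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    if np.ptp(lp) == 0:
        raise ValueError("linear predictor is constant; calibration slope undefined")
    X = np.column_stack([np.ones_like(lp), lp])
    res = fit_logit(X, y, names=["(intercept)", "lp"], check_separation=False)
    return float(res.coef[1])


def citl(linear_predictors, outcomes) -> float:
    """Calibration-in-the-large: intercept with the slope fixed at 1 (offset fit)."""
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_classes(y)
    X = np.ones((len(lp), 1))
    res = fit_logit(X, y, names=["(intercept)"], offset=lp, check_separation=False)
    return float(res.coef[0])


def calibration_curve(
    predictions, outcomes, groups: int = 10
) -> tuple[list[CalibrationPoint], bool]:
    """Equal-size groups by ranked prediction: (mean predicted, observed fraction, size).

    Ties are broken by a stable sort.  Returns the points and a flag that is
    True when the predictions collapse into fewer effective groups than asked
    (e.g. constant predictions).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if len(p) < groups:
        raise ValueError(f"need at least {groups} observations for {groups} groups")
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, groups)
    points = [
        CalibrationPoint(float(p[b].mean()), float(y[b].mean()), int(len(b))) for b in bins
    ]
    degenerate = len({round(pt.mean_predicted, 12) for pt in points}) < groups
    return points, degenerate


def smoothed_calibration(
    predictions, outcomes, grid: np.ndarray | None = None, window_fraction: float = 0.3
):
    """Windowed local mean of the outcome on the logit scale of the predictions.

    A light-weight smoother for calibration plots: for each grid probability,
    averages outcomes whose prediction's logit falls within a window spanning
    the given fraction of the observed logit range.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    eps = 1e-12
    lp = logit(np.clip(p, eps, 1 - eps))
    if grid is None:
        grid = np.linspace(p.min(), p.max(), 50)
    gl = logit(np.clip(grid, eps, 1 - eps))
    half = window_fraction * np.ptp(lp) / 2.0 if np.ptp(lp) > 0 else 0.5
    out = np.full(len(grid), np.nan)
    for i, g in enumerate(gl):
        mask = np.abs(lp - g) <= half
        if mask.any():
            out[i] = y[mask].mean()
    return np.asarray(grid), out


def evaluate(predictions, linear_predictors, outcomes, groups: int = 10) -> PerformanceReport:
    """Full performance report: C, slope, CITL and the grouped calibration curve."""
    y = np.asarray(outcomes, dtype=float)
    points, degenerate = calibration_curve(predictions, y, groups=groups)
    return PerformanceReport(
        c_statistic=c_statistic(predictions, y),
        calibration_slope=calibration_slope(linear_predictors, y),
        citl=citl(linear_predictors, y),
        n=len(y),
        events=int(y.sum()),
        calibration_curve=points,
        degenerate_calibration=degenerate,
    )
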