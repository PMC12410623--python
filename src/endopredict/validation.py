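"""Internal (bootstrap optimism) and external validation of developed models.

Bootstrap internal validation follows the standard resampling recipe: the full
development procedure (fractional-polynomial selection plus backward
elimination, unless ``replay_selection`` is off) is repeated in each of B
bootstrap resamples; each resample's model is scored both on the resample
(apparent) and on the original data (test), and the average apparent-minus-test
gap is the optimism.  Optimism-adjusted performance is the original model's
apparent performance minus that optimism, for the C-statistic, calibration
slope and calibration-in-the-large.  The optimism-adjusted calibration slope
doubles as the uniform shrinkage factor: the final model multiplies every slope
coefficient by it and re-estimates the intercept by maximum likelihood with the
shrunken linear predictor as a fixed offset, so the mean predicted probability
matches the observed event fraction again.

External validation scores a frozen model card on a new cohort — stored
transforms, centerings and coefficients, no refitting — and reports the same
statistics plus the grouped calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._logit import ConvergenceError, SeparationError, fit_logit
from .cards import ModelCard, design_matrix
from .cohort import CohortTable, complete_case, outcome_indicator
from .development import DevelopmentSpec, FittedModel, backward_eliminate, develop, fit_logistic
from .performance import PerformanceReport, c_statistic, calibration_curve, calibration_slope, citl


@dataclass(frozen=True)
class ValidationSpec:
    """Bootstrap settings: replicate count B, seed, and whether each resample
    replays the full selection procedure (the defensible default) or only
    refits the original model's terms (fast mode)."""

    B: int = 200
    seed: int = 0
    replay_selection: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class InternalValidationResult:
    apparent: PerformanceReport
    optimism: dict
    adjusted: dict
    shrinkage: float
    B_effective: int
    redrawn_resamples: int
    skipped_resamples: int
    model: FittedModel
    card: ModelCard

    def to_dict(self) -> dict:
        return {
            "apparent": self.apparent.to_dict(),
            "optimism": self.optimism,
            "adjusted": self.adjusted,
            "shrinkage": self.shrinkage,
            "B_effective": self.B_effective,
            "redrawn_resamples": self.redrawn_resamples,
            "skipped_resamples": self.skipped_resamples,
        }


def _metrics(model: FittedModel, df, y) -> dict:
    lp = model.linear_predictor(df)
    return {
        "c_statistic": c_statistic(lp, y),
        "calibration_slope": calibration_slope(lp, y) if np.ptp(lp) > 0 else np.nan,
        "citl": citl(lp, y),
    }


def _prepared(table: CohortTable, dev_spec: DevelopmentSpec):
    """Complete-case rows with a defined improvement indicator."""
    from .cohort import screen_missingness

    retained, _ = screen_missingness(table, dev_spec.candidates)
    cc, _ = complete_case(table, retained)
    y_all, _ = outcome_indicator(cc)
    keep = y_all.notna()
    df = cc.df[keep].reset_index(drop=True)
    y = y_all[keep].to_numpy(dtype=float)
    return CohortTable(df, cc.codebook), y


def bootstrap_validate(
    table: CohortTable, dev_spec: DevelopmentSpec, val_spec: ValidationSpec = ValidationSpec()
) -> InternalValidationResult:
    """Optimism-adjusted performance plus the uniform-shrinkage model card.

    Deterministic given ``val_spec.seed``.  Resamples whose outcome collapses
    to a single class are redrawn (keeping B fixed, logged); resamples whose
    model fails to converge or separates are skipped and the effective B
    reported.
    """
    rng = np.random.default_rng(val_spec.seed)
    model = develop(table, dev_spec)
    prepared, y = _prepared(table, dev_spec)
    df = prepared.df
    n = len(df)

    lp = model.linear_predictor(df)
    points, degenerate = calibration_curve(_expit(lp), y)
    apparent = PerformanceReport(
        c_statistic=c_statistic(lp, y),
        calibration_slope=1.0,  # slope of a model on its own development data is 1 by construction
        citl=0.0,
        n=n,
        events=int(y.sum()),
        calibration_curve=points,
        degenerate_calibration=degenerate,
    )

    opt = {"c_statistic": [], "calibration_slope": [], "citl": []}
    redrawn = skipped = 0
    for _ in range(val_spec.B):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redrawn += 1
        else:  # pragma: no cover - pathological
            raise RuntimeError("could not draw a two-class bootstrap resample")
        dfb = df.iloc[idx].reset_index(drop=True)
        try:
            if val_spec.replay_selection:
                boot_model = _develop_on(dfb, yb, prepared, dev_spec)
            else:
                boot_model = fit_logistic(model.terms, dfb, yb)
        except (SeparationError, ConvergenceError):
            skipped += 1
            continue
        app = _metrics(boot_model, dfb, yb)
        test = _metrics(boot_model, df, y)
        for k in opt:
            if np.isfinite(app[k]) and np.isfinite(test[k]):
                opt[k].append(app[k] - test[k])

    optimism = {k: float(np.mean(v)) if v else 0.0 for k, v in opt.items()}
    adjusted = {
        "c_statistic": apparent.c_statistic - optimism["c_statistic"],
        "calibration_slope": 1.0 - optimism["calibration_slope"],
        "citl": 0.0 - optimism["citl"],
    }
    shrinkage = float(adjusted["calibration_slope"])
    card = apply_shrinkage(
        model,
        shrinkage,
        prepared,
        y=y,
        performance={
            "apparent": {"c_statistic": apparent.c_statistic, "calibration_slope": 1.0, "citl": 0.0},
            "optimism": optimism,
            "optimism_adjusted": adjusted,
        },
    )
    return InternalValidationResult(
        apparent=apparent,
        optimism=optimism,
        adjusted=adjusted,
        shrinkage=shrinkage,
        B_effective=val_spec.B - skipped,
        redrawn_resamples=redrawn,
        skipped_resamples=skipped,
        model=model,
        card=card,
    )


def _develop_on(dfb, yb, prepared: CohortTable, dev_spec: DevelopmentSpec) -> FittedModel:
    """Replay FP selection + backward elimination on a bootstrap resample."""
    from .development import _term_for

    terms = []
    for name in ("baseline_score", *[c for c in dev_spec.candidates if c in dfb.columns]):
        t = _term_for(name, prepared.codebook, dfb, yb, dev_spec)
        if t is not None:
            terms.append(t)
    mandatory_cols = tuple(
        prepared.codebook.baseline_column if m == "baseline_score" else m for m in dev_spec.mandatory
    )
    return backward_eliminate(terms, dfb, yb, mandatory=mandatory_cols, alpha=dev_spec.alpha)


def apply_shrinkage(
    model: FittedModel,
    S: float,
    table: CohortTable,
    y: np.ndarray | None = None,
    name: str = "",
    performance: dict | None = None,
) -> ModelCard:
    """Uniform shrinkage: scale all slope coefficients by S, re-estimate the intercept.

    The intercept is refitted by maximum likelihood with the shrunken linear
    predictor as a fixed offset, which makes the mean predicted probability
    equal the observed event fraction on the development data.  S outside
    (0, 1] is accepted with a warning (it indicates underfitting or a
    pathological validation run).
    """
    import warnings

    if not (0.0 < S <= 1.0):
        warnings.warn(f"shrinkage factor {S:.3f} outside (0, 1]", stacklevel=2)
    if y is None:
        y_ser, _ = outcome_indicator(table)
        if y_ser.isna().any():
            raise ValueError("table has undefined outcomes; filter first")
        y = y_ser.to_numpy(dtype=float)
    df = table.df
    X, _ = design_matrix(model.terms, df)
    shrunken_lp_no_intercept = X @ (S * model.coef)
    res = fit_logit(
        np.ones((len(df), 1)), y, names=["(intercept)"], offset=shrunken_lp_no_intercept
    )
    new_intercept = float(res.coef[0])
    shrunk = FittedModel(
        terms=model.terms,
        intercept=new_intercept,
        intercept_se=float(res.se[0]),
        coef=S * model.coef,
        se=model.se * S,
        column_names=model.column_names,
        llf=res.llf,
        n=model.n,
        events=model.events,
        outcome=model.outcome,
        scale=model.scale,
    )
    return shrunk.to_card(
        name=name or f"{model.outcome}_shrunken", shrinkage=float(S), performance=performance
    )


def validate_external(card: ModelCard, table: CohortTable, groups: int = 10) -> PerformanceReport:
    """Score a frozen card on an external cohort: C, slope, CITL, calibration curve.

    The card is never refitted or mutated; missing predictor columns or
    categorical levels unseen in the card's encoding raise errors naming them.
    """
    needed = [t.name for t in card.terms]
    missing = [c for c in needed if c not in table.df.columns and c != "baseline_score"]
    if missing:
        raise KeyError(f"external cohort is missing predictors required by the card: {missing}")
    cc, _ = complete_case(table, [c for c in needed if c in table.codebook.predictors])
    y_all, _ = outcome_indicator(cc)
    keep = y_all.notna()
    df = cc.df[keep].reset_index(drop=True)
    y = y_all[keep].to_numpy(dtype=float)
    lp = card.linear_predictor(df)
    p = _expit(lp)
    points, degenerate = calibration_curve(p, y, groups=groups)
    return PerformanceReport(
        c_statistic=c_statistic(lp, y),
        calibration_slope=calibration_slope(lp, y),
        citl=citl(lp, y),
        n=len(y),
        events=int(y.sum()),
        calibration_curve=points,
        degenerate_calibration=degenerate,
    )


def _expit(x):
    from scipy.special import expit

    return expit(x)
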