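"""Model development: FP1 transform selection, ML logistic fitting, backward elimination.

The development recipe, applied per outcome:

1. Screen candidate predictors for excessive missingness and keep complete cases.
2. For each continuous candidate, choose a first-degree fractional-polynomial
   (FP1) transform by the closed-test procedure: the best of the eight
   canonical powers is compared with the null model (2 df) — if not significant
   at alpha the predictor is excluded — and then with the linear term (1 df) —
   if not significantly better, linear is kept.  The baseline score is a
   mandatory covariate, so for it only the FP-versus-linear stage runs.
3. Fit the full logistic model and run backward elimination: repeatedly drop
   the non-mandatory term with the largest likelihood-ratio p-value at or above
   alpha (categorical terms as whole blocks), refitting until every remaining
   non-mandatory term has p < alpha.  The default alpha of 0.157 acts as a
   proxy for best-subset selection by AIC.

Transforms are selected once, before elimination, and frozen during it
(one-pass mfp-style cycling); ``cycle=True`` repeats selection and elimination
until the chosen model is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._logit import CollinearityError, ConvergenceError, LogitResult, SeparationError, fit_logit
from .cards import (
    BinaryTerm,
    CategoricalTerm,
    ContinuousTerm,
    ModelCard,
    Term,
    design_matrix,
)
from .cohort import CohortTable, complete_case, outcome_indicator, screen_missingness
from .transforms import FP1_POWERS, FPTransform, apply_fp, positivity_shift_scale

__all__ = [
    "DevelopmentSpec",
    "FittedModel",
    "apply_fp",
    "fit_logistic",
    "select_fp1",
    "backward_eliminate",
    "develop",
    "SeparationError",
    "CollinearityError",
    "ConvergenceError",
]

DEFAULT_ALPHA = 0.157


@dataclass(frozen=True)
class DevelopmentSpec:
    """What to develop: outcome, candidates, mandatory covariates, alpha, FP powers."""

    candidates: tuple[str, ...]
    mandatory: tuple[str, ...] = ("baseline_score",)
    alpha: float = DEFAULT_ALPHA
    fp_powers: tuple[float, ...] = FP1_POWERS
    select_transforms: bool = True
    cycle: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        missing = set(self.mandatory) - set(self.candidates) - {"baseline_score"}
        if missing:
            raise ValueError(f"mandatory predictors must be candidates: {sorted(missing)}")


@dataclass
class FittedModel:
    """A maximum-likelihood logistic model over typed terms.

    Coefficients are log-odds per design column (continuous terms per unit of
    the transformed variable); ``exp(coef)`` is the reportable odds ratio and
    the 95% CI is ``exp(coef +/- 1.96 se)``.
    """

    terms: list[Term]
    intercept: float
    intercept_se: float
    coef: np.ndarray
    se: np.ndarray
    column_names: list[str]
    llf: float
    n: int
    events: int
    outcome: str = ""
    scale: str = "vas"

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(self.terms, df)
        return self.intercept + X @ self.coef

    def odds_ratios(self) -> dict[str, dict]:
        out = {}
        for name, c, s in zip(self.column_names, self.coef, self.se):
            lo, hi = c - 1.96 * s, c + 1.96 * s
            out[name] = {"or": float(np.exp(c)), "ci": [float(np.exp(lo)), float(np.exp(hi))]}
        return out

    def to_card(self, name: str = "", shrinkage: float | None = None, performance: dict | None = None) -> ModelCard:
        """Freeze as a model card (terms carry their fitted coefficients)."""
        terms: list[Term] = []
        i = 0
        for t in self.terms:
            k = len(t.column_names)
            cs, ss = self.coef[i : i + k], self.se[i : i + k]
            if isinstance(t, ContinuousTerm):
                terms.append(replace(t, coef=float(cs[0]), se=float(ss[0])))
            elif isinstance(t, BinaryTerm):
                terms.append(replace(t, coef=float(cs[0]), se=float(ss[0])))
            else:
                terms.append(
                    CategoricalTerm(
                        t.name, t.reference, t.levels, tuple(map(float, cs)), tuple(map(float, ss))
                    )
                )
            i += k
        return ModelCard(
            name=name or f"{self.outcome}_developed",
            outcome=self.outcome,
            scale=self.scale,
            terms=terms,
            intercept=float(self.intercept),
            intercept_se=float(self.intercept_se),
            n=self.n,
            events=self.events,
            shrinkage=shrinkage,
            performance=performance or {},
            odds_ratios=self.odds_ratios(),
        )


def _fit_terms(terms: list[Term], df: pd.DataFrame, y: np.ndarray) -> LogitResult:
    X, names = design_matrix(terms, df)
    X = np.column_stack([np.ones(len(df)), X]) if X.size or len(df) else np.ones((len(df), 1))
    return fit_logit(X, y, names=["(intercept)", *names])


def fit_logistic(terms: list[Term], table_or_df, y=None, outcome: str = "", scale: str = "vas") -> FittedModel:
    """Maximum-likelihood logistic fit of an improvement indicator on typed terms.

    Accepts either a :class:`CohortTable` (the indicator is derived from its
    dichotomization rule) or a DataFrame plus an explicit 0/1 vector.
    Separation and collinearity raise typed errors rather than returning
    runaway coefficients.
    """
    if isinstance(table_or_df, CohortTable):
        df = table_or_df.df
        yy, _ = outcome_indicator(table_or_df)
        if yy.isna().any():
            raise ValueError(
                "table contains records with undefined or missing outcome; "
                "apply complete_case / baseline-zero exclusion first"
            )
        y = yy.to_numpy(dtype=float)
        outcome = outcome or table_or_df.codebook.outcome
        scale = table_or_df.codebook.scale
    else:
        df = table_or_df
        if y is None:
            raise ValueError("a DataFrame requires an explicit outcome vector")
        y = np.asarray(y, dtype=float)
    res = _fit_terms(list(terms), df, y)
    return FittedModel(
        terms=list(terms),
        intercept=float(res.coef[0]),
        intercept_se=float(res.se[0]),
        coef=res.coef[1:],
        se=res.se[1:],
        column_names=res.names[1:],
        llf=res.llf,
        n=res.n,
        events=res.events,
        outcome=outcome,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# FP1 selection (closed test)


def select_fp1(
    x: np.ndarray,
    y: np.ndarray,
    adjustment: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    powers: tuple[float, ...] = FP1_POWERS,
    mandatory: bool = False,
) -> FPTransform | None:
    """Closed-test FP1 selection for one continuous predictor.

    (i) the best FP1 power (by deviance) is tested against the null model at
    alpha on 2 df: if not significant the predictor is excluded (``None``) —
    skipped for mandatory predictors; (ii) the best FP1 is tested against the
    linear term at alpha on 1 df: if not significantly better, linear is kept.
    The returned transform uses the positivity shift/scale convention and is
    centered at the sample mean of the transformed values.  A selected linear
    transform is reported on the raw scale (shift 0, scale 1), which is the
    same model in a different parameterisation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shift, scale = positivity_shift_scale(x)
    z = (x + shift) / scale
    if np.min(z) <= 0:
        raise ValueError("values remain non-positive after the maximal allowed shift")
    if len(np.unique(z)) < 3:
        raise ValueError("need at least 3 distinct values for FP selection")
    n = len(x)
    adj = np.empty((n, 0)) if adjustment is None else np.asarray(adjustment, dtype=float)
    ones = np.ones((n, 1))

    def dev(cols: np.ndarray | None) -> float:
        X = ones if cols is None else np.column_stack([ones, cols])
        if adj.size:
            X = np.column_stack([X, adj])
        return -2.0 * fit_logit(X, y, check_separation=False).llf

    dev_null = dev(None)
    devs = {}
    for p in powers:
        fx = np.log(z) if p == 0.0 else z**p
        devs[p] = dev(fx[:, None])
    best_p = min(devs, key=lambda p: (devs[p], abs(p - 1.0)))
    dev_best, dev_lin = devs[best_p], devs[1.0]

    if not mandatory:
        p_any = sps.chi2.sf(dev_null - dev_best, df=2)
        if p_any >= alpha:
            return None
    p_nonlin = sps.chi2.sf(dev_lin - dev_best, df=1)
    if p_nonlin >= alpha or best_p == 1.0:
        t0 = FPTransform(shift=0.0, scale=1.0, power=1.0, center=0.0)
        return replace(t0, center=float(np.mean(x)))
    t0 = FPTransform(shift=shift, scale=scale, power=best_p, center=0.0)
    fx = np.log(z) if best_p == 0.0 else z**best_p
    return replace(t0, center=float(np.mean(fx)))


# ---------------------------------------------------------------------------
# backward elimination


def backward_eliminate(
    terms: list[Term],
    df: pd.DataFrame,
    y: np.ndarray,
    mandatory: tuple[str, ...] = ("baseline_score",),
    alpha: float = DEFAULT_ALPHA,
    trace: list | None = None,
) -> FittedModel:
    """Backward elimination by likelihood-ratio tests on whole term blocks.

    Repeatedly refits without each non-mandatory term, computes the LR p-value
    of the dropped block (df = number of its design columns), and removes the
    term with the largest p-value >= alpha; stops when all remaining
    non-mandatory terms are significant.  Deterministic given the data.
    """
    terms = list(terms)
    y = np.asarray(y, dtype=float)
    while True:
        full = _fit_terms(terms, df, y)
        candidates = []
        for j, t in enumerate(terms):
            if t.name in mandatory:
                continue
            reduced = terms[:j] + terms[j + 1 :]
            red = _fit_terms(reduced, df, y)
            lr = 2.0 * (full.llf - red.llf)
            pval = sps.chi2.sf(max(lr, 0.0), df=len(t.column_names))
            candidates.append((pval, j, t, red))
        drop = [c for c in candidates if c[0] >= alpha]
        if not drop:
            break
        pval, j, t, _red = max(drop, key=lambda c: (c[0], -c[1]))
        if trace is not None:
            trace.append({"dropped": t.name, "p_value": float(pval)})
        terms = terms[:j] + terms[j + 1 :]
    res = _fit_terms(terms, df, y)
    return FittedModel(
        terms=terms,
        intercept=float(res.coef[0]),
        intercept_se=float(res.se[0]),
        coef=res.coef[1:],
        se=res.se[1:],
        column_names=res.names[1:],
        llf=res.llf,
        n=res.n,
        events=res.events,
    )


# ---------------------------------------------------------------------------
# full pipeline


def _term_for(name: str, codebook, df: pd.DataFrame, y: np.ndarray, spec: DevelopmentSpec) -> Term | None:
    cb = codebook
    if name == "baseline_score" or name == cb.baseline_column:
        kind = "continuous"
    else:
        kind = cb.predictors[name].type
    col = cb.baseline_column if name == "baseline_score" else name
    if kind == "binary":
        return BinaryTerm(col, coef=0.0)
    if kind == "categorical":
        pspec = cb.predictors[name]
        others = tuple(l for l in pspec.levels if l != pspec.reference)
        return CategoricalTerm(col, pspec.reference, others, tuple(0.0 for _ in others))
    x = df[col].to_numpy(dtype=float)
    if spec.select_transforms:
        t = select_fp1(
            x, y, alpha=spec.alpha, powers=spec.fp_powers, mandatory=(name in spec.mandatory or col in spec.mandatory)
        )
        if t is None:
            return None
        return ContinuousTerm(col, t, coef=0.0)
    return ContinuousTerm(col, FPTransform(center=float(np.mean(x))), coef=0.0)


def develop(table: CohortTable, spec: DevelopmentSpec, log: dict | None = None) -> FittedModel:
    """Run the whole development recipe on a cohort table.

    Missingness screening -> complete-case filter -> outcome dichotomization
    (records with undefined relative reduction excluded, count logged) -> FP1
    selection for continuous candidates -> backward elimination with the
    baseline score mandatory.  Returns the final fitted model; ``log`` (if
    given) collects the filter and elimination trail.
    """
    log = log if log is not None else {}
    retained, screen_log = screen_missingness(table, spec.candidates)
    log["missingness"] = screen_log
    cc, cc_log = complete_case(table, retained)
    log["complete_case"] = cc_log
    y_all, dich_log = outcome_indicator(cc)
    log["dichotomization"] = dich_log
    keep = y_all.notna()
    df = cc.df[keep].reset_index(drop=True)
    y = y_all[keep].to_numpy(dtype=float)
    cc = CohortTable(df, cc.codebook)

    def build_terms() -> list[Term]:
        terms: list[Term] = []
        for name in ("baseline_score", *retained):
            t = _term_for(name, cc.codebook, df, y, spec)
            if t is not None:
                terms.append(t)
            elif name in spec.mandatory:  # pragma: no cover - mandatory never excluded
                raise RuntimeError(f"mandatory predictor {name} excluded by FP selection")
        return terms

    mandatory_cols = tuple(
        cc.codebook.baseline_column if m == "baseline_score" else m for m in spec.mandatory
    )
    trace: list = []
    terms = build_terms()
    model = backward_eliminate(terms, df, y, mandatory=mandatory_cols, alpha=spec.alpha, trace=trace)
    if spec.cycle:
        for _ in range(5):
            kept_names = {t.name for t in model.terms}
            spec_pass = replace(spec, cycle=False)
            again = backward_eliminate(
                [t for t in build_terms() if t.name in kept_names or t.name in mandatory_cols],
                df,
                y,
                mandatory=mandatory_cols,
                alpha=spec.alpha,
                trace=trace,
            )
            if {t.name for t in again.terms} == kept_names:
                model = again
                break
            model = again
    log["elimination"] = trace
    model.outcome = cc.codebook.outcome
    model.scale = cc.codebook.scale
    return model
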