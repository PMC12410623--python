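"""Seeded synthetic cohorts emulating national endometriosis-surgery registries.

Real patient-level data behind the published models are not publicly deposited,
so the pipeline is exercised on synthetic cohorts that are *structurally*
faithful: the twelve candidate predictors with their types (continuous
age/BMI/baseline score, binary treated-location flags, three-level conceiving
and smoking variables), a symptomatic baseline-score distribution, outcome
status drawn from a specified model card's logistic linear predictor, and
follow-up scores back-constructed so that re-dichotomizing the generated scores
reproduces the drawn improvement status exactly.

Continuous covariate means default to the development-sample means implied by
the published centering constants (age about 34-35 years, BMI about 26 kg/m²);
spreads, prevalences and level probabilities are not published and are package
defaults, overridable per predictor. Missingness is MCAR per predictor; the
complete-case analysis stance makes richer mechanisms out of scope.

All randomness flows from a single integer seed through one generator stream,
so an identical :class:`GeneratorSpec` yields a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cards import ModelCard
from .cohort import Codebook, CohortTable, OutcomeRule, PredictorSpec


@dataclass(frozen=True)
class Continuous:
    """Truncated-normal continuous covariate (units of the predictor)."""

    mean: float
    sd: float
    lo: float
    hi: float
    decimals: int | None = None  # round recorded values, e.g. 1 for BMI
    missing: float = 0.0


@dataclass(frozen=True)
class BetaScaled:
    """Beta(a, b) scaled to [lo, hi]; used for skewed bounded scores."""

    a: float
    b: float
    lo: float
    hi: float
    decimals: int | None = 0  # scores recorded as integers by default
    missing: float = 0.0


@dataclass(frozen=True)
class Binary:
    prevalence: float
    missing: float = 0.0


@dataclass(frozen=True)
class Categorical:
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    reference: str | None = None  # defaults to first level
    missing: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"level probabilities must lie in [0,1] and sum to 1, got {self.probs}")
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must have equal length")


CovariateDist = Continuous | BetaScaled | Binary | Categorical
CovariateConfig = Mapping[str, CovariateDist]


def default_covariates() -> dict[str, CovariateDist]:
    """Default covariate distributions for registry-like cohorts.

    Age and BMI centre on the published development-sample means; binary
    treated-location prevalences and the three-level conceiving/smoking
    probabilities are package defaults (unpublished in the source data).
    """
    return {
        "age": Continuous(mean=34.5, sd=7.0, lo=16.0, hi=65.0, decimals=1),
        "bmi": Continuous(mean=26.0, sd=5.0, lo=15.0, hi=50.0, decimals=1),
        "strong_painkillers": Binary(0.35),
        "hormonal_contraception": Binary(0.40),
        "ovarian_usl_endo": Binary(0.30),
        "hysterectomy": Binary(0.10),
        "oocds": Binary(0.25),
        "peritoneal_endo": Binary(0.45),
        "bowel_deep_endo": Binary(0.12),
        "conceiving": Categorical(
            ("not_trying", "trying_lt18m", "trying_ge18m"), (0.70, 0.12, 0.18)
        ),
        "smoking": Categorical(("smoker", "ex_smoker", "never_smoker"), (0.25, 0.25, 0.50)),
    }


def default_baseline_dist(scale: str) -> CovariateDist:
    """Baseline score distribution: symptomatic (high) VAS via a right-shifted
    beta on [0, 10]; QoL baseline truncated to [0, 90] so that a 10-point gain
    is always realisable."""
    if scale == "vas":
        return BetaScaled(a=5.0, b=2.0, lo=0.0, hi=10.0, decimals=0)
    return Continuous(mean=50.0, sd=18.0, lo=0.0, hi=90.0, decimals=0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to draw one reproducible cohort.

    ``truth`` supplies the linear predictor from which improvement status is
    drawn Bernoulli(expit(intercept_shift + slope_factor * lp)); the shift and
    factor default to the identity and exist to construct miscalibrated
    external-validation cohorts.  ``followup_noise`` is the SD (score points)
    of the follow-up score around the value implied by the drawn status;
    follow-up scores are kept inside the status-consistent interval so the
    dichotomization rule reproduces the drawn status exactly.
    """

    n: int
    seed: int
    truth: ModelCard
    covariates: CovariateConfig | None = None
    baseline: CovariateDist | None = None
    followup_noise: float = 1.0
    intercept_shift: float = 0.0
    slope_factor: float = 1.0
    rule: OutcomeRule | None = None
    missingness: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.slope_factor <= 0:
            raise ValueError("slope_factor must be positive")


def make_external_shift(
    spec: GeneratorSpec, intercept_shift: float, slope_factor: float = 1.0
) -> GeneratorSpec:
    """A spec whose outcome law is ``intercept_shift + slope_factor * lp``.

    Used to build miscalibrated external cohorts: at large n, validating the
    original card against such a cohort recovers calibration-in-the-large of
    about ``intercept_shift`` (for slope_factor 1) and a calibration slope of
    about ``slope_factor``.
    """
    if slope_factor <= 0:
        raise ValueError("slope_factor must be positive")
    return replace(
        spec,
        intercept_shift=spec.intercept_shift + intercept_shift,
        slope_factor=spec.slope_factor * slope_factor,
    )


def _draw(name: str, dist: CovariateDist, n: int, rng: np.random.Generator):
    if isinstance(dist, Continuous):
        a = (dist.lo - dist.mean) / dist.sd
        b = (dist.hi - dist.mean) / dist.sd
        vals = stats.truncnorm.rvs(a, b, loc=dist.mean, scale=dist.sd, size=n, random_state=rng)
        if dist.decimals is not None:
            vals = np.round(vals, dist.decimals)
            vals = np.clip(vals, dist.lo, dist.hi)
        return vals
    if isinstance(dist, BetaScaled):
        vals = dist.lo + (dist.hi - dist.lo) * rng.beta(dist.a, dist.b, size=n)
        if dist.decimals is not None:
            vals = np.round(vals, dist.decimals)
            vals = np.clip(vals, dist.lo, dist.hi)
        return vals
    if isinstance(dist, Binary):
        return (rng.random(n) < dist.prevalence).astype(float)
    if isinstance(dist, Categorical):
        idx = rng.choice(len(dist.levels), size=n, p=dist.probs)
        return np.array(dist.levels, dtype=object)[idx]
    raise TypeError(f"unknown covariate distribution for {name!r}: {dist!r}")


def _force_vas_status(
    baseline: np.ndarray, followup: np.ndarray, improved: np.ndarray, thr: float
) -> np.ndarray:
    """Nudge follow-up scores by ulps so that the inclusive relative-reduction
    rule reproduces the drawn status exactly despite floating-point rounding
    at the boundary (records cluster at exactly baseline*(1-thr))."""
    f = followup.copy()
    ok = baseline > 0
    for _ in range(60):
        status = np.zeros_like(f)
        status[ok] = ((baseline[ok] - f[ok]) / baseline[ok] >= thr).astype(float)
        wrong = ok & (status != improved)
        if not wrong.any():
            break
        # improved but reads as not: lower the score; the reverse: raise it
        f[wrong & (improved == 1)] = np.nextafter(f[wrong & (improved == 1)], -np.inf)
        f[wrong & (improved == 0)] = np.nextafter(f[wrong & (improved == 0)], np.inf)
        f = np.clip(f, 0.0, 10.0)
    else:  # pragma: no cover - a few ulps always suffice
        raise RuntimeError("could not reconcile follow-up scores with drawn status")
    return f


def _followup_vas(
    baseline: np.ndarray, improved: np.ndarray, thr: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Follow-up VAS consistent with the drawn status.

    Improved: reduction fraction in [thr, 1] -> followup in [0, baseline*(1-thr)].
    Not improved: reduction below thr -> followup in (baseline*(1-thr), 10].
    Baseline 0 (status undefined under the relative rule) gets followup 0.
    """
    n = len(baseline)
    # implied central values: a typical good response vs a typical non-response
    implied = np.where(improved == 1, baseline * (1 - thr) * 0.5, baseline)
    out = implied + rng.normal(0.0, noise, size=n)
    hi_improved = baseline * (1 - thr)
    lo_not = np.nextafter(hi_improved, np.inf)
    out = np.where(improved == 1, np.clip(out, 0.0, hi_improved), np.clip(out, lo_not, 10.0))
    out = _force_vas_status(baseline, out, improved.astype(float), thr)
    out = np.where(baseline == 0, 0.0, out)
    return out


def _followup_qol(
    baseline: np.ndarray, improved: np.ndarray, thr: float, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Follow-up QoL consistent with the drawn status: gain >= thr iff improved."""
    implied = np.where(improved == 1, baseline + thr + 5.0, baseline)
    out = implied + rng.normal(0.0, noise, size=len(baseline))
    lo_improved = baseline + thr
    hi_not = np.nextafter(lo_improved, -np.inf)
    out = np.where(
        improved == 1, np.clip(out, lo_improved, 100.0), np.clip(out, 0.0, np.minimum(hi_not, 100.0))
    )
    # reconcile any floating-point boundary rounding with the drawn status
    f = out.copy()
    for _ in range(60):
        status = (f - baseline >= thr).astype(float)
        wrong = status != improved
        if not wrong.any():
            break
        f[wrong & (improved == 1)] = np.nextafter(f[wrong & (improved == 1)], np.inf)
        f[wrong & (improved == 0)] = np.nextafter(f[wrong & (improved == 0)], -np.inf)
        f = np.clip(f, 0.0, 100.0)
    else:  # pragma: no cover
        raise RuntimeError("could not reconcile follow-up scores with drawn status")
    return f


def generate(spec: GeneratorSpec) -> CohortTable:
    """Draw a cohort of ``spec.n`` records from the truth card's logistic law.

    Returns a :class:`CohortTable` whose codebook is derived from the covariate
    configuration. Identical specs produce identical tables.
    """
    card = spec.truth
    rng = np.random.default_rng(spec.seed)
    cov = dict(spec.covariates if spec.covariates is not None else default_covariates())
    missing_card = [p for p in card.predictor_names if p != "baseline_score" and p not in cov]
    if missing_card:
        raise KeyError(f"covariate config does not cover card predictors: {missing_card}")
    baseline_dist = spec.baseline if spec.baseline is not None else default_baseline_dist(card.scale)
    rule = spec.rule or OutcomeRule(
        kind="vas_reduction" if card.scale == "vas" else "qol_gain"
    )

    df = pd.DataFrame({"id": [f"P{i:06d}" for i in range(spec.n)]})
    df["baseline_score"] = _draw("baseline_score", baseline_dist, spec.n, rng)
    for name, dist in cov.items():
        df[name] = _draw(name, dist, spec.n, rng)

    lp = card.linear_predictor(df)
    p = expit(spec.intercept_shift + spec.slope_factor * lp)
    improved = (rng.random(spec.n) < p).astype(int)

    baseline = df["baseline_score"].to_numpy(dtype=float)
    if card.scale == "vas":
        follow = _followup_vas(baseline, improved, rule.vas_threshold, spec.followup_noise, rng)
    else:
        follow = _followup_qol(baseline, improved, rule.qol_threshold, spec.followup_noise, rng)
    df["followup_score"] = follow

    # MCAR missingness, applied to recorded values after outcome generation
    rates = dict(spec.missingness)
    for name, dist in cov.items():
        rate = rates.get(name, getattr(dist, "missing", 0.0))
        if rate > 0:
            mask = rng.random(spec.n) < rate
            df.loc[mask, name] = np.nan if not isinstance(dist, Categorical) else None

    predictors = {}
    for name, dist in cov.items():
        if isinstance(dist, (Continuous, BetaScaled)):
            predictors[name] = PredictorSpec(type="continuous")
        elif isinstance(dist, Binary):
            predictors[name] = PredictorSpec(type="binary")
        else:
            ref = dist.reference or dist.levels[0]
            predictors[name] = PredictorSpec(type="categorical", levels=dist.levels, reference=ref)
    codebook = Codebook(outcome=card.outcome, scale=card.scale, predictors=predictors)
    return CohortTable(df, codebook)


def event_probabilities(spec: GeneratorSpec, table: CohortTable) -> np.ndarray:
    """Per-record improvement probabilities under the spec's generative law.

    Recomputed from the covariates in ``table`` (missingness-free columns are
    assumed); useful as a Monte-Carlo expectation for the realised event rate.
    """
    lp = spec.truth.linear_predictor(table.df)
    return expit(spec.intercept_shift + spec.slope_factor * lp)
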