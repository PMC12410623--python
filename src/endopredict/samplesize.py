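"""Minimum sample size for developing a binary-outcome prediction model, and
Table-style model reports.

The sample-size calculation implements the three standard criteria of Riley
and colleagues for logistic prediction models with ``p`` candidate parameters,
an anticipated Cox-Snell R-squared and an anticipated outcome prevalence:

1. Targeted global shrinkage: the expected uniform shrinkage factor should be
   at least ``S_target`` (0.9 by default), giving
   ``n >= p / ((S - 1) * ln(1 - R2_CS / S))``.
2. Small apparent-versus-adjusted optimism in R-squared: at most ``delta_R2``
   (0.05) of the maximum achievable Cox-Snell R-squared at the anticipated
   prevalence, which implies its own shrinkage requirement plugged into the
   same formula.
3. Precise estimation of the overall risk: a 95% confidence half-width of at
   most ``margin_phi`` (0.05) around the prevalence,
   ``n >= (1.96 / margin)^2 * phi * (1 - phi)``.

Each criterion is rounded up separately; the minimum sample size is their
maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cards import ModelCard


def max_cox_snell_r2(phi: float) -> float:
    """Maximum achievable Cox-Snell R-squared for a binary outcome with prevalence phi:
    1 - (phi^phi * (1-phi)^(1-phi))^2."""
    if not (0.0 < phi < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    ll0 = phi * math.log(phi) + (1.0 - phi) * math.log(1.0 - phi)
    return 1.0 - math.exp(2.0 * ll0)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the minimum-sample-size calculation."""

    p: int
    R2_CS: float
    phi: float
    S_target: float = 0.9
    delta_R2: float = 0.05
    margin_phi: float = 0.05

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not (0.0 < self.S_target < 1.0):
            raise ValueError("S_target must lie in (0, 1)")
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must lie in (0, 1)")
        if not (0.0 < self.R2_CS < max_cox_snell_r2(self.phi)):
            raise ValueError(
                f"R2_CS must lie in (0, {max_cox_snell_r2(self.phi):.4f}) for prevalence {self.phi}"
            )


@dataclass(frozen=True)
class SampleSizeResult:
    n_shrinkage: int
    n_optimism: int
    n_intercept: int
    spec: SampleSizeSpec

    @property
    def n_min(self) -> int:
        return max(self.n_shrinkage, self.n_optimism, self.n_intercept)

    @property
    def events_implied(self) -> int:
        return math.ceil(self.n_min * self.spec.phi)

    @property
    def binding_criterion(self) -> str:
        ns = {
            "shrinkage": self.n_shrinkage,
            "r2_optimism": self.n_optimism,
            "intercept_precision": self.n_intercept,
        }
        return max(ns, key=ns.get)

    def to_dict(self) -> dict:
        return {
            "n_shrinkage": self.n_shrinkage,
            "n_optimism": self.n_optimism,
            "n_intercept": self.n_intercept,
            "n_min": self.n_min,
            "events_implied": self.events_implied,
            "binding_criterion": self.binding_criterion,
        }


def _n_for_shrinkage(p: int, R2_CS: float, S: float) -> int:
    return math.ceil(p / ((S - 1.0) * math.log(1.0 - R2_CS / S)))


def riley_min_n(spec: SampleSizeSpec) -> SampleSizeResult:
    """All three minimum-sample-size criteria and their maximum."""
    n1 = _n_for_shrinkage(spec.p, spec.R2_CS, spec.S_target)
    # criterion 2: the shrinkage implied by an acceptable optimism delta_R2
    # against the maximum achievable Cox-Snell R2 at this prevalence
    max_r2 = max_cox_snell_r2(spec.phi)
    S2 = spec.R2_CS / (spec.R2_CS + spec.delta_R2 * max_r2)
    n2 = _n_for_shrinkage(spec.p, spec.R2_CS, S2)
    n3 = math.ceil((1.96 / spec.margin_phi) ** 2 * spec.phi * (1.0 - spec.phi))
    return SampleSizeResult(n1, n2, n3, spec)


# ---------------------------------------------------------------------------
# model reports


def _fmt_or(entry: dict) -> str:
    o = entry["or"]
    ci = entry.get("ci")
    def fmt(v: float) -> str:
        return f"{v:.3g}" if v < 0.1 else f"{v:.2f}"
    if ci:
        return f"{fmt(o)} ({fmt(ci[0])} to {fmt(ci[1])})"
    return fmt(o)


def render_model_report(card: ModelCard) -> str:
    """A Markdown report mirroring the published layout: one row per term with
    OR (95% CI), the intercept with its SE, transformations in readable
    algebra, and the performance block.  Percentages are recomputed from the
    stored counts, never stored."""
    from .cards import CategoricalTerm, ContinuousTerm

    lines = [f"# Model: {card.name}", ""]
    lines.append(f"Outcome: {card.outcome} ({'VAS pain' if card.scale == 'vas' else 'quality of life'})")
    if card.n is not None and card.events is not None:
        lines.append(f"Observations: {card.n}")
        lines.append(f"Improvement events: {card.events} ({card.event_percent:.1f})")
    if card.shrinkage is not None:
        lines.append(f"Uniform shrinkage factor applied: {card.shrinkage:.3f}")
    lines += ["", "| Term | OR (95% CI) |", "| --- | --- |"]

    ors = dict(card.odds_ratios)

    def lookup(label: str, coef: float, se: float | None) -> str:
        if label in ors:
            return _fmt_or(ors[label])
        o = math.exp(coef)
        if se is not None:
            return _fmt_or({"or": o, "ci": [math.exp(coef - 1.96 * se), math.exp(coef + 1.96 * se)]})
        return _fmt_or({"or": o})

    transform_rows = []
    for t in card.terms:
        if isinstance(t, ContinuousTerm):
            lines.append(f"| {t.name} | {lookup(t.name, t.coef, t.se)} |")
            transform_rows.append((t.name, t.transform.describe(t.name)))
        elif isinstance(t, CategoricalTerm):
            for lvl, coef, se in zip(
                t.levels, t.coefs_by_level, t.ses_by_level or [None] * len(t.levels)
            ):
                label = f"{t.name}[{lvl}]"
                lines.append(f"| {t.name}: {t.reference} vs {lvl} | {lookup(label, coef, se)} |")
        else:
            lines.append(f"| {t.name} | {lookup(t.name, t.coef, t.se)} |")
    if card.intercept_se is not None:
        lines.append(f"| Intercept (SE) | {card.intercept:.2f} ({card.intercept_se:.2f}) |")
    else:
        lines.append(f"| Intercept | {card.intercept:.2f} |")

    if transform_rows:
        lines += ["", "Transformations:", ""]
        for name, desc in transform_rows:
            lines.append(f"- {name}: {desc}")

    lines.append("")
    perf = card.performance or {}
    adj = perf.get("optimism_adjusted")
    if adj:
        lines.append("Optimism-adjusted performance:")
        lines.append(f"- C-statistic: {adj['c_statistic']:.3f}")
        lines.append(f"- Calibration slope: {adj['calibration_slope']:.3f}")
        lines.append(f"- CITL: {adj['citl']:.3f}")
    else:
        lines.append("Performance: apparent only (no internal-validation block recorded)")
    return "\n".join(lines) + "\n"
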