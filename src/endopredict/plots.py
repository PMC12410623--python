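"""Plot helpers: calibration plots and net-benefit (decision) curves.

Thin wrappers over matplotlib; importing this module requires the ``plots``
extra. Each function accepts an existing Axes or creates its own, and returns
the Axes so callers can compose panels.
"""

from __future__ import annotations

from .decision import DecisionCurve
from .performance import PerformanceReport


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 5))
    return ax


def plot_calibration(report: PerformanceReport, ax=None, label: str | None = None):
    """Grouped calibration plot: observed fraction vs mean predicted, with the diagonal."""
    ax = _ax(ax)
    xs = [p.mean_predicted for p in report.calibration_curve]
    ys = [p.observed_fraction for p in report.calibration_curve]
    ax.plot([0, 1], [0, 1], "--", color="grey", linewidth=1, label="ideal")
    ax.plot(xs, ys, "o-", label=label or "model")
    ax.set_xlabel("Mean predicted probability")
    ax.set_ylabel("Observed event fraction")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    ax.set_title(
        f"C={report.c_statistic:.3f}, slope={report.calibration_slope:.2f}, CITL={report.citl:.2f}"
    )
    return ax


def plot_decision_curve(curve: DecisionCurve, ax=None, label: str = "model"):
    """Net benefit of model vs treat-all and treat-none across thresholds."""
    ax = _ax(ax)
    ax.plot(curve.thresholds, curve.net_benefit_model, label=label)
    ax.plot(curve.thresholds, curve.net_benefit_all, label="treat all", linestyle="--")
    ax.plot(curve.thresholds, curve.net_benefit_none, label="treat none", linestyle=":", color="grey")
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.set_ylim(bottom=max(-0.05, float(curve.net_benefit_model.min()) - 0.02))
    ax.legend()
    return ax
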