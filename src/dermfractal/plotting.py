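"""Diagnostic plots: log-log box-count fits and ROC curves."""

from __future__ import annotations

import numpy as np

from .fractal import FractalEstimate
from .grouping import RocCurve


def plot_loglog_fit(estimate: FractalEstimate, ax=None):
    """Scatter of log N(eps) vs log(1/eps) with the fitted line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = -np.log(estimate.series.epsilons.astype(float))
    y = np.log(estimate.series.counts.astype(float))
    ax.plot(x, y, "o", label="box counts")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(
        xs,
        estimate.db * xs + estimate.intercept,
        "-",
        label=f"fit: $D_b$ = {estimate.db:.4f} ($R^2$ = {estimate.r_squared:.4f})",
    )
    ax.set_xlabel(r"$\log(1/\epsilon)$")
    ax.set_ylabel(r"$\log N(\epsilon)$")
    ax.legend()
    return ax


def plot_roc(curve: RocCurve, ax=None):
    """ROC curve (FPR vs TPR) with the chance diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fpr = 1.0 - curve.points["specificity"].to_numpy()
    tpr = curve.points["sensitivity"].to_numpy()
    order = np.argsort(fpr)
    ax.plot(fpr[order], tpr[order], "-", label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"positive: {curve.positive_label}")
    ax.legend()
    return ax
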