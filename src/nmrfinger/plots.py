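"""Basic figures: OPLS score plot, ROC curve, metabolite box plots.

Thin matplotlib wrappers; every function returns the Axes so callers can
restyle. Import is local to keep headless batch runs cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _ax(ax):
    if ax is None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def score_plot(model, ax=None):
    """Predictive score vs first orthogonal score, one dot per subject."""
    ax = _ax(ax)
    t_orth = model.T_orth[:, 0] if model.n_orthogonal else np.zeros_like(model.t)
    colors = np.where(model.t >= 0, "tab:blue", "tab:red")
    ax.scatter(model.t, t_orth, c=colors, edgecolor="k", linewidth=0.3)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("predictive score t")
    ax.set_ylabel("orthogonal score t_o")
    return ax


def roc_plot(points: np.ndarray, auc: float, ax=None):
    ax = _ax(ax)
    ax.plot(points[:, 0], points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8, ls="--")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {auc:.2f}")
    return ax


def metabolite_boxplot(levels: pd.DataFrame, is_responder, metabolite: str, ax=None):
    ax = _ax(ax)
    mask = np.asarray(is_responder, bool)
    data = [levels.loc[mask, metabolite], levels.loc[~mask, metabolite]]
    ax.boxplot(data, tick_labels=["responders", "non-responders"])
    ax.set_ylabel(f"{metabolite} (normalized area)")
    return ax
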