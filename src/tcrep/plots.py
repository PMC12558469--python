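"""Figure helpers for the standard pipeline visualizations.

Thin matplotlib wrappers over the analysis outputs: clonality-by-group box
plots, ROC curves of the external test, and the z-scored cluster-property
heatmap. Each function returns the Figure so callers can save or embed it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def gini_by_group(div: pd.DataFrame, groups: pd.Series, column: str = "gini_downsampled"):
    """Box plot of per-sample clonality stratified by diagnosis group."""
    levels = sorted(groups.unique())
    data = [div.loc[groups[groups == g].index, column].to_numpy() for g in levels]
    fig, ax = plt.subplots(figsize=(1.2 * len(levels) + 1.5, 3.5))
    ax.boxplot(data, tick_labels=levels)
    ax.set_ylabel("Gini coefficient")
    ax.set_xlabel("group")
    fig.tight_layout()
    return fig


def roc_curve(scores, labels, label: str = "model"):
    """Empirical ROC of one score vector (positive class = 1)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(y[order] == 1)
    fps = np.cumsum(y[order] == 0)
    tpr = np.concatenate([[0], tps / max(1, (y == 1).sum())])
    fpr = np.concatenate([[0], fps / max(1, (y == 0).sum())])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    return fig


def property_heatmap(zscores: pd.DataFrame):
    """Clusters × properties heatmap of z-normalized mean physical properties."""
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.08 * len(zscores) + 1)))
    if len(zscores):
        order = zscores.sum(axis=1).sort_values().index
        im = ax.imshow(zscores.loc[order].to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-3, vmax=3)
        fig.colorbar(im, ax=ax, label="z-score")
        ax.set_xticks(range(len(zscores.columns)), zscores.columns, rotation=45,
                      ha="right")
    ax.set_ylabel("cluster")
    fig.tight_layout()
    return fig
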