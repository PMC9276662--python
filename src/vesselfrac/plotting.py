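"""Plain plotting helpers (box-and-whisker of the group dimensions and
the risk-score scatter). Requires matplotlib (``pip install vesselfrac[plot]``)."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_df_by_group", "plot_qrisk_scatter"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(4, 4))
    return ax


def plot_df_by_group(cohort: pd.DataFrame, ax=None):
    """Box-and-whisker plot of the averaged dimension per subject group."""
    ax = _axes(ax)
    groups = sorted(cohort["group"].unique())
    data = [cohort.loc[cohort["group"] == g, "df_mean"] for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel(r"$D_f(w)$")
    return ax


def plot_qrisk_scatter(cohort: pd.DataFrame, ax=None):
    """Scatter of the QRISK2 score against the averaged dimension."""
    ax = _axes(ax)
    for g, marker in zip(sorted(cohort["group"].unique()), "os^v"):
        sel = cohort["group"] == g
        ax.scatter(cohort.loc[sel, "qrisk2"], cohort.loc[sel, "df_mean"],
                   marker=marker, label=g, alpha=0.8)
    ax.set_xlabel("QRISK2 score (%)")
    ax.set_ylabel(r"$D_f(w)$")
    ax.legend()
    return ax
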