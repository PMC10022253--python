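"""Scatter-matrix plots of joint volumes against shoulder motions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats import MOTION_COLUMNS, VOLUME_COLUMNS, pearson  # noqa: E402

__all__ = ["plot_scatter_matrix"]


def plot_scatter_matrix(cohort, motion_cols=MOTION_COLUMNS, volume_cols=VOLUME_COLUMNS,
                        path: str | Path | None = None):
    """Motion x volume scatter grid with the Pearson r annotated per panel.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    nrows, ncols = len(motion_cols), len(volume_cols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.6 * ncols, 2.4 * nrows),
                             squeeze=False, constrained_layout=True)
    for i, m in enumerate(motion_cols):
        for j, v in enumerate(volume_cols):
            ax = axes[i][j]
            pair = cohort[[v, m]].dropna()
            ax.scatter(pair[v], pair[m], s=8, alpha=0.6, edgecolors="none")
            res = pearson(pair[v], pair[m])
            ax.annotate(f"r={res.r:.2f}\np={res.p:.4f}", xy=(0.03, 0.97),
                        xycoords="axes fraction", va="top", fontsize=7)
            if i == nrows - 1:
                ax.set_xlabel(f"{v} (mL)", fontsize=8)
            if j == 0:
                ax.set_ylabel(m, fontsize=8)
            ax.tick_params(labelsize=7)
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
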