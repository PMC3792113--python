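"""Rendering of the over/under gene-summary matrices as heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

from .meta_summary import GeneSummaryMatrix

_BINS = [0.5, 1.5, 5.5, 10.5]


def plot_summary_matrix(matrix: GeneSummaryMatrix, path: str | Path) -> None:
    """Two-panel heatmap (over / under) of best gene-rank percentiles.

    Colour intensity encodes the percentile class of the best
    above-threshold analysis (1% darkest, then 5%, then 10%); blank cells
    had no above-threshold analysis.
    """
    panels = [("Overexpression", matrix.over, ["#fee0d2", "#fb6a4a", "#a50f15"][::-1]),
              ("Underexpression", matrix.under, ["#deebf7", "#6baed6", "#08519c"][::-1])]
    fig, axes = plt.subplots(
        2, 1, figsize=(max(6, 0.45 * matrix.over.shape[1]),
                       max(5, 0.3 * matrix.over.shape[0] * 2)),
        constrained_layout=True,
    )
    for ax, (title, mat, colors) in zip(axes, panels):
        cmap = ListedColormap(colors)
        cmap.set_bad("white")
        norm = BoundaryNorm(_BINS, cmap.N)
        data = np.ma.masked_invalid(mat.to_numpy(float))
        im = ax.imshow(data, aspect="auto", cmap=cmap, norm=norm)
        ax.set_title(title)
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
        cbar = fig.colorbar(im, ax=ax, ticks=[1, 3.5, 8])
        cbar.ax.set_yticklabels(["1%", "5%", "10%"])
        cbar.set_label("best gene rank percentile")
    fig.savefig(path, dpi=150)
    plt.close(fig)
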