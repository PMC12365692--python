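"""Optional matplotlib renderings of reliability results."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_reliability_curves(
    curves_by_group: Mapping[str, Sequence], threshold: float = 0.8, ax=None
):
    """Group-mean TRC vs post-censored duration, one line per motion group."""
    from .trc import group_mean_curve

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for group, curves in sorted(curves_by_group.items()):
        grid = curves[0].grid_minutes
        ax.plot(grid, group_mean_curve(curves), marker="o", label=group)
    ax.axhline(threshold, ls="--", color="gray", lw=1)
    ax.set_xlabel("post-censored duration (min)")
    ax.set_ylabel("FC test-retest correlation")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax


def plot_icc_heatmap(matrix: np.ndarray, labels: Sequence[str] | None = None, ax=None):
    """ICC matrix heatmap with the conventional category boundaries."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(matrix, vmin=0, vmax=1, cmap="plasma")
    plt.colorbar(im, ax=ax, ticks=[0, 0.4, 0.6, 0.75, 1.0], label="ICC(2,1)")
    if labels is not None:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    return ax
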