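"""Matplotlib helpers for metaprofile curves and clustered heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .profiles import ClusterResult, ProfileMatrix, metaprofile


def plot_metaprofile(
    matrices: dict[str, ProfileMatrix], path: str | Path, title: str = ""
) -> None:
    """Overlayed per-bin mean density curves, one line per labelled matrix."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, m in matrices.items():
        x = np.arange(-m.window, m.window, m.bin_size) + m.bin_size / 2
        ax.plot(x, metaprofile(m), label=label)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("mean read density")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(
    matrix: ProfileMatrix,
    clusters: ClusterResult | None,
    path: str | Path,
    title: str = "",
) -> None:
    """Anchor x bin heatmap, rows ordered by cluster then signal."""
    order = clusters.row_order if clusters is not None else np.arange(len(matrix.anchors))
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(
        matrix.values[order],
        aspect="auto",
        interpolation="nearest",
        cmap="viridis",
        extent=(-matrix.window, matrix.window, len(order), 0),
    )
    if clusters is not None:
        labels = clusters.labels[order]
        for r in np.flatnonzero(np.diff(labels)) + 1:
            ax.axhline(r, color="white", linewidth=0.6)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("anchors")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.6, label="read density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
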