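"""Minimal plotting helpers (correlation-matrix heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_correlation_matrix"]


def plot_correlation_matrix(corr: pd.DataFrame, path=None, ax=None):
    """Heatmap of a Pearson correlation matrix of model parameters."""
    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * len(corr) + 2, 0.4 * len(corr) + 2))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
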