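"""Optional diagnostics plots (gene dendrogram, module-trait heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

__all__ = ["plot_gene_dendrogram", "plot_module_trait_heatmap"]


def plot_gene_dendrogram(results, path=None, ax=None):
    """Gene dendrogram with module color bar underneath."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    dd = dendrogram(results.linkage_matrix, no_labels=True, ax=ax,
                    color_threshold=0, above_threshold_color="k")
    order = dd["leaves"]
    labels = results.assignment.iloc[order].values
    colors = [lab if lab != "grey" and not lab.startswith(("M", "module_"))
              else "grey" for lab in labels]
    for i, c in enumerate(colors):
        try:
            ax.bar(5 + i * 10, height=-0.03 * results.linkage_matrix[:, 2].max(),
                   width=10, color=c, bottom=0, clip_on=False)
        except ValueError:
            pass
    ax.set_ylabel("1 - TOM")
    ax.set_xticks([])
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_module_trait_heatmap(assoc_results, path=None, ax=None):
    """Heatmap of module eigengene-trait partial correlations."""
    wide = assoc_results.correlation_matrix()
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.8 * wide.shape[1],
                                      1 + 0.45 * wide.shape[0]))
    im = ax.imshow(wide.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(np.arange(wide.shape[1]), wide.columns, rotation=45, ha="right")
    ax.set_yticks(np.arange(wide.shape[0]), wide.index)
    sig = assoc_results.table.pivot(index="module", columns="trait",
                                    values="significant").loc[wide.index, wide.columns]
    for i in range(wide.shape[0]):
        for j in range(wide.shape[1]):
            mark = "*" if bool(sig.iloc[i, j]) else ""
            ax.text(j, i, f"{wide.iloc[i, j]:.2f}{mark}", ha="center",
                    va="center", fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="partial r")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
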