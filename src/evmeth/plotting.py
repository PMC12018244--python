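"""Minimal diagnostics: PCA scatter and Venn-cell count bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .integration import VennPartition
from .preprocess import PairedDesign, PCAResult


def plot_pca(pca: PCAResult, design: PairedDesign | None = None, ax=None):
    """Scatter samples on PC1/PC2, colored by group when a design is given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    scores = pca.top_scores(2)
    if design is not None:
        cmap = plt.get_cmap("tab10")
        for i, grp in enumerate(design.groups):
            for sample, marker in ((grp.treated, "^"), (grp.control, "o")):
                xy = scores.loc[sample]
                ax.scatter(xy.iloc[0], xy.iloc[1] if scores.shape[1] > 1 else 0,
                           color=cmap(i), marker=marker, label=sample)
        ax.legend(fontsize=7, loc="best")
    else:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1] if scores.shape[1] > 1 else 0)
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    return ax


def plot_venn_cell_counts(partition: VennPartition, ax=None):
    """Bar chart of exclusive-cell cardinalities of one Venn partition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    cells = sorted(
        partition.cardinalities().items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    )
    labels = ["∩".join(sorted(s)) for s, _ in cells]
    ax.bar(range(len(cells)), [n for _, n in cells])
    ax.set_xticks(range(len(cells)), labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("genes")
    return ax
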