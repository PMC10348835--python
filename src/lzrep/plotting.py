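"""Matplotlib views of per-sequence diagnostics."""

from __future__ import annotations

import numpy as np

from .centrality import GeneUsageMatrix, VariationCurve


def plot_variation_curve(curve: VariationCurve, ax=None):
    """Step plot of out-degrees along a sequence's subpattern path."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.5 * len(curve.subpatterns)), 3))
    x = np.arange(len(curve.subpatterns))
    ax.step(x, curve.out_degrees, where="mid")
    ax.set_xticks(x, curve.subpatterns, rotation=90)
    ax.set_ylabel("out-degree")
    ax.set_title(f"LZ-Centrality = {curve.lz_centrality:.2f}")
    return ax


def plot_gene_variation(
    v_matrix: GeneUsageMatrix, j_matrix: GeneUsageMatrix, axes=None
):
    """Allele-by-edge probability heat maps; never-observed cells in black,
    full-path allele labels in red."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(12, 4))
    for ax, mat in zip(axes, (v_matrix, j_matrix)):
        data = mat.probabilities.to_numpy(dtype=float)
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("black")
        im = ax.imshow(np.ma.masked_invalid(data), cmap=cmap, vmin=0, vmax=1, aspect="auto")
        ax.set_xticks(range(len(mat.edges)), mat.edges, rotation=90)
        ax.set_yticks(range(len(mat.alleles)), mat.alleles)
        for label in ax.get_yticklabels():
            if label.get_text() in mat.full_path_alleles:
                label.set_color("red")
        ax.set_title(f"{mat.gene} allele usage")
        ax.figure.colorbar(im, ax=ax, label="P(allele | edge)")
    return axes
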