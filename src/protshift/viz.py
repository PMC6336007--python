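"""Convenience rendering of the directional-imbalance heat map.

Upper-left triangle: log2 of the directed substitution ratio for each
residue pair (red = favored in the foreground clade, blue = depleted);
lower-right triangle: the BH-adjusted p-value on a -log10 scale. Pairs
never observed in one direction are hatched grey. This is a convenience
view, not part of the analysis contract.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .substitution_stats import ImbalanceResult, SubstitutionCountMatrix


def plot_imbalance_heatmap(
    matrix: SubstitutionCountMatrix,
    results: Sequence[ImbalanceResult],
    path: str | Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = 20
    log2_grid = np.full((n, n), np.nan)
    q_grid = np.full((n, n), np.nan)
    for r in results:
        i, j = AA_INDEX[r.residue_a], AA_INDEX[r.residue_b]
        if not math.isnan(r.log2_ratio):
            log2_grid[min(i, j), max(i, j)] = r.log2_ratio
        q_grid[max(i, j), min(i, j)] = -math.log10(max(r.q_bh, 1e-300))
    fig, ax = plt.subplots(figsize=(8, 8))
    vmax = np.nanmax(np.abs(log2_grid)) if np.isfinite(log2_grid).any() else 1.0
    ax.imshow(log2_grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    im2 = ax.imshow(q_grid, cmap="viridis")
    ax.set_xticks(range(n), list(AMINO_ACIDS))
    ax.set_yticks(range(n), list(AMINO_ACIDS))
    ax.set_xlabel("residue (foreground side above diagonal)")
    ax.set_ylabel("residue (reference side above diagonal)")
    ax.set_title("Directional substitution imbalance (upper: log2 ratio, lower: -log10 q)")
    fig.colorbar(im2, ax=ax, shrink=0.7, label="-log10 q (lower triangle)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
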