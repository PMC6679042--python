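"""Chromosome track plots: island boxes per breed, gene positions as vertical lines."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .islands import OverlapRegion, ROHIsland
from .loci import GeneInterval
from .stratification import PCAResult


def plot_tracks(
    islands: list[ROHIsland],
    overlap_regions: list[OverlapRegion] | None,
    genes: list[GeneInterval] | None,
    chrom: str,
    bp_range: tuple[int, int],
    ax: "plt.Axes | None" = None,
):
    """One horizontal lane per breed with island boxes; genes as labelled vlines.

    Lanes are sorted alphabetically by breed for a deterministic layout; only
    breeds with at least one island intersecting the requested range get a
    lane. Returns the figure.
    """
    lo, hi = bp_range
    in_range = [
        i
        for i in islands
        if i.chrom == chrom and i.start_bp <= hi and i.end_bp >= lo
    ]
    breeds = sorted({i.breed for i in in_range})
    if ax is None:
        fig, ax = plt.subplots(figsize=(10, max(2, 0.5 * len(breeds) + 1.5)))
    else:
        fig = ax.figure
    lane = {b: j for j, b in enumerate(breeds)}
    for isl in in_range:
        y = lane[isl.breed]
        ax.add_patch(
            Rectangle(
                (isl.start_bp / 1e6, y - 0.35),
                max(isl.length_bp, 1) / 1e6,
                0.7,
                label=None,
            )
        )
    for region in overlap_regions or []:
        if region.chrom != chrom or region.end_bp < lo or region.start_bp > hi:
            continue
        ax.axvspan(
            region.start_bp / 1e6, region.end_bp / 1e6, alpha=0.12, color="grey"
        )
    for gene in genes or []:
        if gene.chrom != chrom or gene.end_bp < lo or gene.start_bp > hi:
            continue
        mid = (gene.start_bp + gene.end_bp) / 2 / 1e6
        ax.axvline(mid, linestyle="--", linewidth=0.8, color="black")
        ax.text(
            mid, len(breeds) - 0.3, gene.gene_symbol, rotation=90, fontsize=7,
            va="bottom", ha="center",
        )
    ax.set_xlim(lo / 1e6, hi / 1e6)
    ax.set_ylim(-0.5, max(len(breeds) - 0.5, 0.5) + 0.6)
    ax.set_yticks(range(len(breeds)))
    ax.set_yticklabels(breeds)
    ax.set_xlabel(f"chromosome {chrom} position (Mb)")
    ax.set_title(f"ROH islands on chromosome {chrom}")
    return fig


def plot_pca(pca: PCAResult, breed_of: dict[str, str], pc_x: int = 0, pc_y: int = 1):
    """Scatter of two principal components coloured by breed."""
    fig, ax = plt.subplots(figsize=(7, 6))
    breeds = sorted({breed_of[s] for s in pca.samples})
    for breed in breeds:
        idx = [i for i, s in enumerate(pca.samples) if breed_of[s] == breed]
        ax.scatter(
            pca.coordinates[idx, pc_x],
            pca.coordinates[idx, pc_y],
            s=12,
            label=breed,
        )
    ax.set_xlabel(f"PC{pc_x + 1} ({pca.variance_fraction[pc_x]:.1%})")
    ax.set_ylabel(f"PC{pc_y + 1} ({pca.variance_fraction[pc_y]:.1%})")
    ax.legend(fontsize=7, ncols=2)
    return fig
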