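"""Candidate-locus statistics: genotype frequencies, exact HWE test, gene overlap.

The Hardy-Weinberg test is the exact conditional test: given the observed
allele counts, the heterozygote count follows

    P(n_AB = h | N, n_A)  =  2^h * N! / (n_AA! h! n_BB!) * n_A! n_B! / (2N)!

over heterozygote counts h of the same parity as n_A, and the two-sided
p-value sums the probabilities of all tables no more probable than the
observed one. Probabilities are computed in exact rational arithmetic, so
the returned p-value is exact up to the final float conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .errors import ValidationError
from .islands import ROHIsland
from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one SNP in one breed."""

    breed: str
    snp_id: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    @property
    def n_typed(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class GeneInterval:
    """One annotated gene: symbol and 1-based inclusive genomic interval."""

    gene_symbol: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValidationError(f"gene {self.gene_symbol}: start > end")


def genotype_frequencies(
    panel: GenotypePanel, snp_id: str, include_missing: bool = False
) -> pd.DataFrame:
    """Per-breed genotype counts and fractions at one SNP.

    Fractions are over non-missing calls by default; with
    ``include_missing=True`` the denominator is the full breed sample and a
    missing fraction column is added.
    """
    hits = panel.snps.index[panel.snps["snp_id"] == snp_id]
    if len(hits) == 0:
        raise ValidationError(f"SNP {snp_id!r} not in panel map")
    col = panel.genotypes[:, hits[0]]
    rows = []
    for breed in panel.breeds:
        idx = panel.breed_sample_indices(breed)
        g = col[idx]
        counts = GenotypeCounts(
            breed=breed,
            snp_id=snp_id,
            n_hom_ref=int((g == 0).sum()),
            n_het=int((g == 1).sum()),
            n_hom_alt=int((g == 2).sum()),
            n_missing=int((g == MISSING).sum()),
        )
        denom = len(idx) if include_missing else max(counts.n_typed, 1)
        row = {
            "breed": breed,
            "snp_id": snp_id,
            "n_hom_ref": counts.n_hom_ref,
            "n_het": counts.n_het,
            "n_hom_alt": counts.n_hom_alt,
            "n_missing": counts.n_missing,
            "f_hom_ref": counts.n_hom_ref / denom,
            "f_het": counts.n_het / denom,
            "f_hom_alt": counts.n_hom_alt / denom,
        }
        if include_missing:
            row["f_missing"] = counts.n_missing / denom
        rows.append(row)
    return pd.DataFrame(rows).set_index("breed")


def _het_probabilities(n_a: int, n_total_alleles: int) -> dict[int, Fraction]:
    """Exact conditional distribution of the heterozygote count given allele counts."""
    n = n_total_alleles // 2
    n_b = n_total_alleles - n_a
    weights: dict[int, Fraction] = {}
    h = n_a % 2
    total = Fraction(0)
    while h <= min(n_a, n_b):
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        if n_aa + h + n_bb == n:
            w = Fraction(2**h * comb(n, n_aa) * comb(n - n_aa, h))
            weights[h] = w
            total += w
        h += 2
    return {h: w / total for h, w in weights.items()}


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one breed/SNP table.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no greater than that of the observed table.
    Always in (0, 1]; a monomorphic table gives exactly 1.
    """
    if counts.n_typed < 1:
        raise ValidationError("HWE test needs at least one typed genotype")
    n_a = 2 * counts.n_hom_ref + counts.n_het
    dist = _het_probabilities(n_a, 2 * counts.n_typed)
    p_obs = dist[counts.n_het]
    p = sum(w for w in dist.values() if w <= p_obs)
    return float(min(p, Fraction(1)))


def genes_in_islands(
    islands: list[ROHIsland], annotation: list[GeneInterval]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Intersect islands with gene intervals (>= 1 bp shared, closed intervals).

    Returns a per-island table of intersecting gene symbols and per-breed
    counts of distinct genes over all of that breed's islands. Chromosome
    label sets that are fully disjoint between islands and annotation raise
    a normalization error (likely naming mismatch, e.g. "chr1" vs "1").
    """
    if islands and annotation:
        isl_chroms = {i.chrom for i in islands}
        ann_chroms = {g.chrom for g in annotation}
        if not isl_chroms & ann_chroms:
            raise ValidationError(
                f"no shared chromosome names between islands {sorted(isl_chroms)} "
                f"and annotation {sorted(ann_chroms)}; harmonize naming"
            )
    rows = []
    per_breed: dict[str, set[str]] = {}
    for isl in islands:
        genes = sorted(
            g.gene_symbol
            for g in annotation
            if g.chrom == isl.chrom
            and g.start_bp <= isl.end_bp
            and isl.start_bp <= g.end_bp
        )
        per_breed.setdefault(isl.breed, set()).update(genes)
        rows.append(
            {
                "breed": isl.breed,
                "chrom": isl.chrom,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "n_genes": len(genes),
                "genes": ",".join(genes),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["breed", "chrom", "start_bp", "end_bp", "n_genes", "genes"]
    )
    return frame, {b: len(s) for b, s in per_breed.items()}


def read_annotation(
    path: str, coords: str = "bed"
) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or TSV (1-based inclusive).

    BED columns: chrom, start, end, name[, score, strand]; TSV columns:
    gene_symbol, chrom, start_bp, end_bp[, strand], no header.
    """
    if coords not in ("bed", "tsv"):
        raise ValidationError("coords must be 'bed' or 'tsv'")
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if coords == "bed":
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(GeneInterval(name, chrom, start + 1, end, strand))
            else:
                name, chrom, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
                strand = parts[4] if len(parts) > 4 else "."
                genes.append(GeneInterval(name, chrom, start, end, strand))
    return genes
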