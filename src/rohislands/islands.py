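"""Breed-level ROH islands: incidence tracks, island calling, cross-breed overlap.

An *incidence track* records, per SNP, the fraction of a breed's genotyped
individuals whose ROH covers that SNP (denominator: the full breed sample,
not only ROH carriers). An *ROH island* is a maximal run of map-contiguous
SNPs whose incidence strictly exceeds the sharing threshold (default: more
than 50% of the breed). Islands of different breeds that overlap by at least
one base pair are linked into *overlap regions* (connected components of the
inter-breed interval-overlap graph); islands in no region are *private*
(breed-specific). No minimum island length, SNP count or overlap length is
imposed.

Intervals are closed on SNP positions: two islands overlap when their
[start_bp, end_bp] intervals share at least one position; abutting
intervals (one ends at x, the other starts at x+1) do not overlap.
Islands are not split at physical gaps — gap control already happened at
segment calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError
from .panel import GenotypePanel
from .roh import ROHSegment, SROHSummary


@dataclass
class IncidenceTrack:
    """Per-SNP ROH-sharing fraction for one breed on one chromosome."""

    breed: str
    chrom: str
    pos_bp: np.ndarray
    fraction: np.ndarray
    n_individuals: int


@dataclass(frozen=True)
class ROHIsland:
    """Maximal supra-threshold run of SNPs in one breed's incidence track."""

    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class OverlapRegion:
    """Connected component of >=1 bp inter-breed island overlaps."""

    chrom: str
    start_bp: int  # union extent
    end_bp: int
    core_start_bp: int  # intersection-like extent (max start / min end)
    core_end_bp: int
    member_breeds: tuple[str, ...]
    member_islands: tuple[ROHIsland, ...]


def incidence_track(
    segments: list[ROHSegment], panel: GenotypePanel, breed: str
) -> list[IncidenceTrack]:
    """Per-chromosome incidence tracks for one breed.

    Each individual contributes at most 1 to every SNP, even if handed
    overlapping segments for the same sample.
    """
    idx = panel.breed_sample_indices(breed)
    if idx.size == 0:
        raise ValidationError(f"breed {breed!r} has no samples in panel")
    members = {panel.samples[i] for i in idx}
    chrom_arr = panel.snps["chrom"].to_numpy()
    pos_arr = panel.snps["pos_bp"].to_numpy()
    tracks: list[IncidenceTrack] = []
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        count = np.zeros(pos.size, dtype=np.int64)
        by_sample: dict[str, np.ndarray] = {}
        for seg in segments:
            if seg.chrom != chrom or seg.sample_id not in members:
                continue
            cov = by_sample.setdefault(
                seg.sample_id, np.zeros(pos.size, dtype=bool)
            )
            lo = np.searchsorted(pos, seg.start_bp, side="left")
            hi = np.searchsorted(pos, seg.end_bp, side="right")
            cov[lo:hi] = True
        for cov in by_sample.values():
            count += cov
        tracks.append(
            IncidenceTrack(
                breed=breed,
                chrom=str(chrom),
                pos_bp=pos,
                fraction=count / idx.size,
                n_individuals=int(idx.size),
            )
        )
    return tracks


def call_islands(track: IncidenceTrack, threshold: float = 0.5) -> list[ROHIsland]:
    """Maximal runs of SNPs with incidence strictly above ``threshold``."""
    above = track.fraction > threshold
    padded = np.concatenate([[False], above, [False]])
    flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
    islands: list[ROHIsland] = []
    for s, e in zip(flips[::2], flips[1::2]):  # run = [s, e)
        islands.append(
            ROHIsland(
                breed=track.breed,
                chrom=track.chrom,
                start_bp=int(track.pos_bp[s]),
                end_bp=int(track.pos_bp[e - 1]),
                n_snps=int(e - s),
                peak_incidence=float(track.fraction[s:e].max()),
            )
        )
    return islands


def call_islands_panel(
    segments: list[ROHSegment],
    panel: GenotypePanel,
    threshold: float = 0.5,
) -> list[ROHIsland]:
    """Islands for every breed of the panel."""
    islands: list[ROHIsland] = []
    for breed in panel.breeds:
        for track in incidence_track(segments, panel, breed):
            islands.extend(call_islands(track, threshold=threshold))
    return islands


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cross_breed_overlaps(islands: list[ROHIsland]) -> list[OverlapRegion]:
    """Connected components of the inter-breed island-overlap graph.

    Edges join islands of *different* breeds whose closed intervals share at
    least one base pair; same-breed islands may still end up in one
    component through a third breed. Components with at least two breeds
    become :class:`OverlapRegion`s spanning the union extent of their
    members (the intersection-like core bounds are also reported).
    """
    uf = _UnionFind(len(islands))
    order = sorted(range(len(islands)), key=lambda i: (islands[i].chrom, islands[i].start_bp))
    # sweep per chromosome: compare each island with actives that still reach it
    active: list[int] = []
    current_chrom: str | None = None
    for i in order:
        isl = islands[i]
        if isl.chrom != current_chrom:
            active = []
            current_chrom = isl.chrom
        active = [j for j in active if islands[j].end_bp >= isl.start_bp]
        for j in active:
            if islands[j].breed != isl.breed:
                uf.union(i, j)
        active.append(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(islands)):
        groups.setdefault(uf.find(i), []).append(i)
    regions: list[OverlapRegion] = []
    for members in groups.values():
        breeds = sorted({islands[i].breed for i in members})
        if len(breeds) < 2:
            continue
        isls = tuple(
            sorted((islands[i] for i in members), key=lambda x: (x.start_bp, x.breed))
        )
        regions.append(
            OverlapRegion(
                chrom=isls[0].chrom,
                start_bp=min(x.start_bp for x in isls),
                end_bp=max(x.end_bp for x in isls),
                core_start_bp=max(x.start_bp for x in isls),
                core_end_bp=min(x.end_bp for x in isls),
                member_breeds=tuple(breeds),
                member_islands=isls,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start_bp))
    return regions


def classify_private(
    islands: list[ROHIsland], overlap_regions: list[OverlapRegion]
) -> pd.DataFrame:
    """Per-breed island/private counts; an island is private iff in no region.

    Returns a DataFrame indexed by breed with columns ``n_islands`` and
    ``n_private`` plus a ``TOTAL`` row; raises :class:`IntegrityError` if a
    region references an island absent from ``islands``.
    """
    island_set = set(islands)
    in_region: set[ROHIsland] = set()
    for region in overlap_regions:
        for isl in region.member_islands:
            if isl not in island_set:
                raise IntegrityError(
                    "overlap region references an island absent from the island list"
                )
            in_region.add(isl)
    rows: dict[str, dict[str, int]] = {}
    for isl in islands:
        row = rows.setdefault(isl.breed, {"n_islands": 0, "n_private": 0})
        row["n_islands"] += 1
        if isl not in in_region:
            row["n_private"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=["n_islands", "n_private"], dtype=int)
    total = pd.DataFrame(
        {
            "n_islands": [len(islands)],
            "n_private": [len(islands) - len(in_region)],
        },
        index=["TOTAL"],
    )
    return pd.concat([df, total])


def summarize_breeds(
    islands: list[ROHIsland],
    sroh_summary: SROHSummary,
    overlap_regions: list[OverlapRegion] | None = None,
    genes_per_breed: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-breed summary: mean S_ROH, summed island length, island/private counts.

    Column set mirrors the usual ROH-island summary table: mean S_ROH (Mb),
    total island length (Mb), island count, private-island count with the
    chromosomes carrying private islands, and (optionally) annotated-gene
    counts.
    """
    in_region: set[ROHIsland] = set()
    for region in overlap_regions or []:
        in_region.update(region.member_islands)
    rows = []
    for breed in sroh_summary.per_breed.index:
        mine = [i for i in islands if i.breed == breed]
        private = [i for i in mine if i not in in_region]
        chroms = sorted({i.chrom for i in private}, key=str)
        rows.append(
            {
                "breed": breed,
                "mean_sroh_mb": float(sroh_summary.per_breed[breed]),
                "sum_islands_mb": sum(i.length_bp for i in mine) / 1e6,
                "n_islands": len(mine),
                "n_private": len(private),
                "private_chroms": ",".join(chroms),
                "n_genes": (genes_per_breed or {}).get(breed, 0),
            }
        )
    return pd.DataFrame(rows).set_index("breed")


# ---------------------------------------------------------------------------
# tabular / BED output


def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "breed": i.breed,
                "chrom": i.chrom,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "start_mb": i.start_bp / 1e6,
                "end_mb": i.end_bp / 1e6,
                "n_snps": i.n_snps,
                "peak_incidence": i.peak_incidence,
                "single_snp": i.n_snps == 1,
            }
            for i in islands
        ],
        columns=[
            "breed",
            "chrom",
            "start_bp",
            "end_bp",
            "start_mb",
            "end_mb",
            "n_snps",
            "peak_incidence",
            "single_snp",
        ],
    )


def regions_to_frame(regions: list[OverlapRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "core_start_bp": r.core_start_bp,
                "core_end_bp": r.core_end_bp,
                "start_mb": r.start_bp / 1e6,
                "end_mb": r.end_bp / 1e6,
                "n_breeds": len(r.member_breeds),
                "breeds": ",".join(r.member_breeds),
                "n_islands": len(r.member_islands),
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "core_start_bp",
            "core_end_bp",
            "start_mb",
            "end_mb",
            "n_breeds",
            "breeds",
            "n_islands",
        ],
    )


def intervals_to_bed(frame: pd.DataFrame, path: str, name_col: str | None = None) -> None:
    """Write 1-based inclusive [start_bp, end_bp] intervals as 0-based half-open BED.

    Conversion: bed_start = start_bp - 1, bed_end = end_bp (the half-open end
    excludes position end_bp + 1, so the covered bases are exactly
    start_bp..end_bp).
    """
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            name = getattr(row, name_col) if name_col else "."
            fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\t{name}\n")
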