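"""Per-individual runs of homozygosity (ROH) under PLINK-style segment rules.

A run of homozygosity is a stretch of consecutive mapped SNPs in one
individual that is (almost) entirely homozygous. Two callers are provided:

* :func:`call_roh_exact` — the reference semantics. A greedy left-to-right
  scan forms maximal non-overlapping candidate runs in which every
  inter-SNP gap is <= ``max_gap_bp``, at most ``max_het_in_segment``
  heterozygotes and ``max_missing_in_segment`` missing calls occur; runs are
  then filtered by minimum length, minimum homozygous-SNP count and SNP
  density. When a heterozygote would exceed the budget of the current run it
  closes that run and opens the next one (the budget-consuming heterozygote
  attaches to the run on its left).

* :func:`call_roh_windowed` — the overlapping-window scan used by PLINK 1.x
  (``--homozyg``): for every window of ``window_snps`` consecutive SNPs a
  hit is recorded if the window contains <= ``window_max_het`` heterozygotes
  and <= ``window_max_missing`` missing calls; a SNP whose covering-window
  hit proportion reaches ``window_hit_threshold`` enters a candidate run,
  and candidate runs are trimmed and filtered with the exact caller's
  segment rules. Chromosomes shorter than one window fall back to the exact
  caller.

Default parameters: segments of at least 500 kb containing more than 80
homozygous SNPs, at most 1 heterozygote and 2 missing calls, at least one
SNP per 50 kb on average, and no inter-SNP gap above 100 kb. Segment length
is ``end_bp - start_bp`` over the first/last SNP of the run (PLINK
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import MISSING, GenotypePanel


@dataclass(frozen=True)
class ROHParams:
    """Segment and window parameters for ROH calling."""

    min_length_bp: int = 500_000
    min_hom_snps: int = 81
    max_het_in_segment: int = 1
    max_missing_in_segment: int = 2
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 100_000
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    #: read "greater than 500 kb" literally (length > min) instead of PLINK's >=
    strict_gt: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.window_hit_threshold <= 1:
            raise ValidationError("window_hit_threshold must be in (0, 1]")
        for name in (
            "min_length_bp",
            "min_hom_snps",
            "max_het_in_segment",
            "max_missing_in_segment",
            "min_density_bp_per_snp",
            "max_gap_bp",
            "window_snps",
            "window_max_het",
            "window_max_missing",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    """One called run of homozygosity in one individual."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _check_map(snp_map: pd.DataFrame) -> None:
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    if len(chrom) < 2:
        return
    # chromosome blocks must be contiguous with strictly increasing positions
    same = chrom[1:] == chrom[:-1]
    block_starts = chrom[np.concatenate([[True], ~same])]
    if len(set(block_starts)) != len(block_starts):
        raise ValidationError("SNP map not grouped by chromosome")
    if not (np.diff(pos)[same] > 0).all():
        raise ValidationError("SNP map positions not strictly increasing within chromosome")


def _greedy_runs(
    geno: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int, int]]:
    """Maximal non-overlapping candidate runs as (start_idx, end_idx, n_het, n_missing)."""
    runs: list[tuple[int, int, int, int]] = []
    n = len(pos)
    if n == 0:
        return runs
    start = 0
    het = int(geno[0] == 1)
    mis = int(geno[0] == MISSING)
    for j in range(1, n):
        g = geno[j]
        dh = int(g == 1)
        dm = int(g == MISSING)
        if (
            pos[j] - pos[j - 1] > params.max_gap_bp
            or het + dh > params.max_het_in_segment
            or mis + dm > params.max_missing_in_segment
        ):
            runs.append((start, j - 1, het, mis))
            start, het, mis = j, dh, dm
        else:
            het += dh
            mis += dm
    runs.append((start, n - 1, het, mis))
    return runs


def _filter_runs(
    runs: list[tuple[int, int, int, int]],
    pos: np.ndarray,
    params: ROHParams,
    sample_id: str,
    chrom: str,
) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    for start, end, het, mis in runs:
        n_snps = end - start + 1
        length = int(pos[end] - pos[start])
        long_enough = (
            length > params.min_length_bp
            if params.strict_gt
            else length >= params.min_length_bp
        )
        if not long_enough:
            continue
        if n_snps - het - mis < params.min_hom_snps:
            continue
        if length / n_snps > params.min_density_bp_per_snp:
            continue
        out.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=chrom,
                start_bp=int(pos[start]),
                end_bp=int(pos[end]),
                n_snps=n_snps,
                n_het=het,
                n_missing=mis,
            )
        )
    return out


def _per_chrom(snp_map: pd.DataFrame):
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(chrom)]])
    for s, e in zip(starts, ends):
        if e > s:
            yield str(chrom[s]), slice(s, e), pos[s:e]


def call_roh_exact(
    genotype_row: np.ndarray,
    snp_map: pd.DataFrame,
    params: ROHParams = ROHParams(),
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Reference ROH caller: greedy maximal runs, then segment filters."""
    _check_map(snp_map)
    segments: list[ROHSegment] = []
    for chrom, sl, pos in _per_chrom(snp_map):
        runs = _greedy_runs(np.asarray(genotype_row)[sl], pos, params)
        segments.extend(_filter_runs(runs, pos, params, sample_id, chrom))
    return segments


def _window_pass(geno: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean per-SNP mask: covering-window hit proportion >= threshold."""
    n = len(geno)
    w = params.window_snps
    het = (geno == 1).astype(np.int64)
    mis = (geno == MISSING).astype(np.int64)
    c_het = np.concatenate([[0], np.cumsum(het)])
    c_mis = np.concatenate([[0], np.cumsum(mis)])
    het_w = c_het[w:] - c_het[:-w]
    mis_w = c_mis[w:] - c_mis[:-w]
    hit = (het_w <= params.window_max_het) & (mis_w <= params.window_max_missing)
    c_hit = np.concatenate([[0], np.cumsum(hit)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_windows = hi - lo + 1
    n_hits = c_hit[hi + 1] - c_hit[lo]
    return n_hits / n_windows >= params.window_hit_threshold


def call_roh_windowed(
    genotype_row: np.ndarray,
    snp_map: pd.DataFrame,
    params: ROHParams = ROHParams(),
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Overlapping-window ROH caller (PLINK-style), sharing the exact segment rules."""
    _check_map(snp_map)
    genotype_row = np.asarray(genotype_row)
    segments: list[ROHSegment] = []
    for chrom, sl, pos in _per_chrom(snp_map):
        geno = genotype_row[sl]
        if len(geno) < params.window_snps:
            # too few SNPs for one window: exact semantics for this chromosome
            runs = _greedy_runs(geno, pos, params)
            segments.extend(_filter_runs(runs, pos, params, sample_id, chrom))
            continue
        passing = _window_pass(geno, params)
        padded = np.concatenate([[False], passing, [False]])
        flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(flips[::2], flips[1::2]):  # candidate run = [s, e)
            runs = _greedy_runs(geno[s:e], pos[s:e], params)
            segments.extend(_filter_runs(runs, pos[s:e], params, sample_id, chrom))
    return segments


def call_roh_panel(
    panel: GenotypePanel,
    params: ROHParams = ROHParams(),
    method: str = "windowed",
) -> list[ROHSegment]:
    """Call ROH for every sample of a panel with the chosen caller."""
    caller = {"windowed": call_roh_windowed, "exact": call_roh_exact}.get(method)
    if caller is None:
        raise ValidationError(f"unknown ROH method {method!r}")
    _check_map(panel.snps)
    segments: list[ROHSegment] = []
    for i, sample in enumerate(panel.samples):
        segments.extend(
            caller(panel.genotypes[i], panel.snps, params, sample_id=sample)
        )
    return segments


def validate_segment(
    segment: ROHSegment,
    genotype_row: np.ndarray,
    snp_map: pd.DataFrame,
    params: ROHParams = ROHParams(),
) -> list[str]:
    """Independently re-check every segment rule; returns violated-rule names.

    Recomputes SNP, heterozygote and missing counts from the genotypes rather
    than trusting the segment's own fields, so it can serve as a post-hoc
    oracle for either caller.
    """
    problems: list[str] = []
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    mask = (chrom == segment.chrom) & (pos >= segment.start_bp) & (pos <= segment.end_bp)
    idx = np.flatnonzero(mask)
    geno = np.asarray(genotype_row)[idx]
    p = pos[idx]
    if len(idx) == 0 or p[0] != segment.start_bp or p[-1] != segment.end_bp:
        problems.append("endpoints_not_snps")
        return problems
    n_snps = len(idx)
    n_het = int((geno == 1).sum())
    n_mis = int((geno == MISSING).sum())
    length = segment.end_bp - segment.start_bp
    if (n_snps, n_het, n_mis) != (segment.n_snps, segment.n_het, segment.n_missing):
        problems.append("counts_mismatch")
    long_enough = (
        length > params.min_length_bp if params.strict_gt else length >= params.min_length_bp
    )
    if not long_enough:
        problems.append("min_length")
    if n_snps - n_het - n_mis < params.min_hom_snps:
        problems.append("min_hom_snps")
    if n_het > params.max_het_in_segment:
        problems.append("max_het")
    if n_mis > params.max_missing_in_segment:
        problems.append("max_missing")
    if length / n_snps > params.min_density_bp_per_snp:
        problems.append("density")
    if n_snps > 1 and int(np.diff(p).max()) > params.max_gap_bp:
        problems.append("max_gap")
    return problems


# ---------------------------------------------------------------------------
# S_ROH summaries


@dataclass
class SROHSummary:
    """Genome length in ROH per sample (Mb) and its mean per breed."""

    per_sample: pd.Series
    per_breed: pd.Series


def sroh(
    segments: list[ROHSegment],
    samples: list[str],
    breed_of: dict[str, str],
) -> SROHSummary:
    """Sum segment lengths per sample (Mb); breed means include ROH-free samples."""
    unlabeled = [s for s in samples if s not in breed_of]
    if unlabeled:
        raise ValidationError(f"samples without breed label: {unlabeled[:5]}")
    totals = dict.fromkeys(samples, 0.0)
    for seg in segments:
        if seg.sample_id not in totals:
            raise ValidationError(f"segment for unknown sample {seg.sample_id!r}")
        totals[seg.sample_id] += seg.length_bp / 1e6
    per_sample = pd.Series(totals, name="sroh_mb")
    breeds = pd.Series({s: breed_of[s] for s in samples})
    per_breed = per_sample.groupby(breeds).mean().rename("mean_sroh_mb")
    return SROHSummary(per_sample=per_sample, per_breed=per_breed)


def segments_to_frame(
    segments: list[ROHSegment], breed_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabular view of segments, mirroring PLINK's .hom column set."""
    rows = [
        {
            "sample_id": s.sample_id,
            "breed": breed_of.get(s.sample_id, "") if breed_of else "",
            "chrom": s.chrom,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_snps": s.n_snps,
            "n_het": s.n_het,
            "n_missing": s.n_missing,
            "length_kb": s.length_bp / 1e3,
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "breed",
            "chrom",
            "start_bp",
            "end_bp",
            "n_snps",
            "n_het",
            "n_missing",
            "length_kb",
        ],
    )
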