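"""Synthetic multi-breed SNP panels with implanted autozygous tracts.

The generator emulates the statistical structure that breed-level ROH-island
analysis assumes: several breeds genotyped on one shared SNP map, background
genotypes in Hardy-Weinberg proportions at per-SNP founder allele
frequencies, and breed-specific autozygous tracts — a single founder
haplotype for which a chosen fraction of a breed's individuals is made
fully homozygous — implanted before per-genotype error and missingness are
applied. The implanted tracts, their haplotypes and their carriers are
returned as a :class:`TruthSet` so downstream callers can be scored against
ground truth.

Reproducibility: every random block (SNP map, each breed's background, each
tract's haplotype, each breed x tract carrier draw, each breed's noise) uses
its own sub-seed derived from the master seed, so changing one breed's size
leaves every other breed's genotypes unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ValidationError
from .panel import MISSING, GenotypePanel
import pandas as pd


@dataclass(frozen=True)
class ImplantSpec:
    """One autozygous tract: genomic interval plus per-breed carrier fractions."""

    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValidationError(
                f"tract on chrom {self.chrom}: start_bp must be < end_bp"
            )
        for breed, f in self.carrier_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(
                    f"carrier fraction {f} for breed {breed!r} outside [0,1]"
                )


@dataclass
class PanelDesign:
    """Full description of a synthetic panel; identical design+seed => identical panel."""

    breeds: list[tuple[str, int]]
    chrom_lengths_bp: dict[str, int]
    snp_spacing_bp: int = 5_000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    tracts: list[ImplantSpec] = field(default_factory=list)
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate, name in (
            (self.genotype_error_rate, "genotype_error_rate"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name}={rate} outside [0,1]")
        if self.snp_spacing_bp <= 0:
            raise ValidationError("snp_spacing_bp must be positive")
        for label, n in self.breeds:
            if n < 1:
                raise ValidationError(f"breed {label!r} needs >= 1 individual")
        labels = [b for b, _ in self.breeds]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate breed labels in design")
        for t in self.tracts:
            if t.chrom not in self.chrom_lengths_bp:
                raise ValidationError(f"tract chromosome {t.chrom!r} not in design")
            if t.end_bp > self.chrom_lengths_bp[t.chrom] or t.start_bp < 1:
                raise ValidationError(
                    f"tract [{t.start_bp}, {t.end_bp}] outside chrom {t.chrom}"
                )
            for breed in t.carrier_fraction:
                if breed not in labels:
                    raise ValidationError(
                        f"tract names unknown breed {breed!r}"
                    )


@dataclass
class TractTruth:
    """Ground truth for one implanted tract."""

    spec: ImplantSpec
    snp_indices: np.ndarray  # panel-wide SNP indices inside the tract
    haplotype: np.ndarray  # allele-2 indicator per tract SNP
    carriers: dict[str, list[str]]  # breed -> carrier sample ids


@dataclass
class TruthSet:
    tracts: list[TractTruth]


def _sub_rng(seed: int, *key: object) -> np.random.Generator:
    """Generator keyed by (seed, *key); strings hashed stably via crc32."""
    words = [int(seed)]
    for k in key:
        words.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(words))


def n_carriers(fraction: float, n: int) -> int:
    """Carrier count = round(fraction * n), round half up."""
    return int(np.floor(fraction * n + 0.5))


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions on [1, length], sorted."""
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def simulate_panel(design: PanelDesign) -> tuple[GenotypePanel, TruthSet]:
    """Generate a multi-breed panel and its truth set from a :class:`PanelDesign`.

    Order of construction: shared SNP map and founder frequencies; per-breed
    Hardy-Weinberg background; tract implanting (carriers set homozygous for
    the founder haplotype); per-breed genotype error (replacement by a
    uniform random dosage) and missingness, in that order.
    """
    map_rng = _sub_rng(design.seed, "map")
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom in design.chrom_lengths_bp:  # dict order is the map order
        length = design.chrom_lengths_bp[chrom]
        n = max(2, int(round(length / design.snp_spacing_bp)))
        pos = _draw_positions(map_rng, length, n)
        chroms.extend([chrom] * len(pos))
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)
    m = pos_all.size
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp_{i:06d}" for i in range(m)],
            "chrom": chroms,
            "pos_bp": pos_all.astype(int),
            "a1": "A",
            "a2": "B",
        }
    )
    lo, hi = design.allele_freq_range
    freq = map_rng.uniform(lo, hi, size=m)

    chrom_arr = np.asarray(chroms)
    samples: list[str] = []
    breed_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    sample_ids_of: dict[str, list[str]] = {}
    for label, n_ind in design.breeds:
        ids = [f"{label}_{i:03d}" for i in range(n_ind)]
        sample_ids_of[label] = ids
        samples.extend(ids)
        breed_of.update({s: label for s in ids})
        bg_rng = _sub_rng(design.seed, "background", label)
        blocks.append(
            bg_rng.binomial(2, freq, size=(n_ind, m)).astype(np.int8)
        )
    geno = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, m), np.int8)
    breed_row0 = {}
    row = 0
    for label, n_ind in design.breeds:
        breed_row0[label] = row
        row += n_ind

    truths: list[TractTruth] = []
    for t_idx, tract in enumerate(design.tracts):
        in_tract = np.flatnonzero(
            (chrom_arr == tract.chrom)
            & (pos_all >= tract.start_bp)
            & (pos_all <= tract.end_bp)
        )
        hap_rng = _sub_rng(design.seed, "haplotype", t_idx)
        hap = (hap_rng.random(in_tract.size) < freq[in_tract]).astype(np.int8)
        carriers: dict[str, list[str]] = {}
        for label, n_ind in design.breeds:
            f = tract.carrier_fraction.get(label, 0.0)
            k = n_carriers(f, n_ind)
            if k == 0:
                continue
            pick_rng = _sub_rng(design.seed, "carriers", label, t_idx)
            chosen = np.sort(pick_rng.choice(n_ind, size=k, replace=False))
            carriers[label] = [sample_ids_of[label][i] for i in chosen]
            rows = breed_row0[label] + chosen
            geno[np.ix_(rows, in_tract)] = (2 * hap)[None, :]
        truths.append(
            TractTruth(
                spec=tract, snp_indices=in_tract, haplotype=hap, carriers=carriers
            )
        )

    for label, n_ind in design.breeds:
        noise_rng = _sub_rng(design.seed, "noise", label)
        rows = slice(breed_row0[label], breed_row0[label] + n_ind)
        if design.genotype_error_rate > 0:
            err = noise_rng.random((n_ind, m)) < design.genotype_error_rate
            repl = noise_rng.integers(0, 3, size=(n_ind, m)).astype(np.int8)
            geno[rows] = np.where(err, repl, geno[rows])
        if design.missing_rate > 0:
            miss = noise_rng.random((n_ind, m)) < design.missing_rate
            geno[rows] = np.where(miss, np.int8(MISSING), geno[rows])

    panel = GenotypePanel(
        snps=snps, samples=samples, breed_of=breed_of, genotypes=geno
    )
    return panel, TruthSet(tracts=truths)


def expected_incidence(spec: ImplantSpec, breed: str, design: PanelDesign) -> float:
    """Expected per-SNP ROH incidence inside a tract for one breed.

    Equals the tract's carrier fraction for that breed; background ROH
    coverage is approximated as zero, which is accurate for default designs
    where independent Hardy-Weinberg draws essentially never produce a
    segment-length run of homozygous calls.
    """
    if breed not in spec.carrier_fraction:
        raise ValidationError(f"breed {breed!r} not named in tract")
    return spec.carrier_fraction[breed]


# ---------------------------------------------------------------------------
# design files


def design_from_dict(cfg: dict) -> PanelDesign:
    tracts = [
        ImplantSpec(
            chrom=str(t["chrom"]),
            start_bp=int(t["start_bp"]),
            end_bp=int(t["end_bp"]),
            carrier_fraction={str(k): float(v) for k, v in t.get("carrier_fraction", {}).items()},
        )
        for t in cfg.get("tracts", [])
    ]
    return PanelDesign(
        breeds=[(str(b), int(n)) for b, n in cfg["breeds"]],
        chrom_lengths_bp={str(c): int(l) for c, l in cfg["chrom_lengths_bp"].items()},
        snp_spacing_bp=int(cfg.get("snp_spacing_bp", 5_000)),
        allele_freq_range=tuple(cfg.get("allele_freq_range", (0.05, 0.95))),
        tracts=tracts,
        genotype_error_rate=float(cfg.get("genotype_error_rate", 0.0)),
        missing_rate=float(cfg.get("missing_rate", 0.0)),
        seed=int(cfg.get("seed", 0)),
    )


def design_from_yaml(path: str) -> PanelDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def write_truth_tsv(truth: TruthSet, path: str) -> None:
    """Tract coordinates, carrier fractions and carrier ids as a TSV."""
    with open(path, "w") as fh:
        fh.write("tract\tchrom\tstart_bp\tend_bp\tbreed\tcarrier_fraction\tcarriers\n")
        for i, t in enumerate(truth.tracts):
            for breed, f in t.spec.carrier_fraction.items():
                ids = ",".join(t.carriers.get(breed, []))
                fh.write(
                    f"{i}\t{t.spec.chrom}\t{t.spec.start_bp}\t{t.spec.end_bp}"
                    f"\t{breed}\t{f}\t{ids}\n"
                )


def demo_design(seed: int = 0) -> PanelDesign:
    """The shipped demonstration design used by the end-to-end examples.

    Twelve breeds of 30 individuals, five 20-Mb chromosomes at ~5 kb SNP
    spacing (~20,000 SNPs), ten real tracts of 2 Mb at carrier fraction 0.8
    (five private, three shared by two breeds, two shared by three breeds)
    plus four decoy tracts at carrier fraction <= 0.4, genotype error 0.002
    and missingness 0.01.
    """
    breeds = [(f"breed_{i:02d}", 30) for i in range(1, 13)]
    chroms = {str(c): 20_000_000 for c in range(1, 6)}
    mb = 1_000_000

    def tract(chrom: str, start_mb: float, frac: dict[str, float]) -> ImplantSpec:
        return ImplantSpec(
            chrom=chrom,
            start_bp=int(start_mb * mb),
            end_bp=int((start_mb + 2.0) * mb),
            carrier_fraction=frac,
        )

    tracts = [
        # five private tracts
        tract("1", 3.0, {"breed_01": 0.8}),
        tract("1", 8.0, {"breed_02": 0.8}),
        tract("2", 3.0, {"breed_03": 0.8}),
        tract("2", 8.0, {"breed_04": 0.8}),
        tract("3", 3.0, {"breed_05": 0.8}),
        # three tracts shared by two breeds
        tract("3", 8.0, {"breed_06": 0.8, "breed_07": 0.8}),
        tract("4", 3.0, {"breed_08": 0.8, "breed_09": 0.8}),
        tract("4", 8.0, {"breed_10": 0.8, "breed_11": 0.8}),
        # two tracts shared by three breeds
        tract("5", 3.0, {"breed_01": 0.8, "breed_06": 0.8, "breed_12": 0.8}),
        tract("5", 8.0, {"breed_02": 0.8, "breed_07": 0.8, "breed_11": 0.8}),
        # decoys: below the >50% sharing threshold, must yield no island
        tract("1", 13.0, {"breed_03": 0.4}),
        tract("2", 13.0, {"breed_05": 0.3}),
        tract("3", 13.0, {"breed_09": 0.4, "breed_10": 0.2}),
        tract("4", 13.0, {"breed_12": 0.4}),
    ]
    return PanelDesign(
        breeds=breeds,
        chrom_lengths_bp=chroms,
        snp_spacing_bp=5_000,
        tracts=tracts,
        genotype_error_rate=0.002,
        missing_rate=0.01,
        seed=seed,
    )
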