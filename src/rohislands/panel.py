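"""Genotype panels: PLINK bed/bim/fam I/O, breed labels, and SNP quality control.

The canonical in-memory object is :class:`GenotypePanel`: a samples x SNPs
matrix of allele-2 dosages (0/1/2) with ``MISSING`` (-1) as a distinct
sentinel, an ordered SNP map, and a breed label per sample.

The binary codec follows the PLINK 1.x bed specification (v1.00 magic
``0x6c 0x1b``, SNP-major mode ``0x01``), two bits per genotype packed four
samples per byte, little-endian within the byte:

    00 -> homozygous allele-1 (dosage 0)
    01 -> missing
    10 -> heterozygous      (dosage 1)
    11 -> homozygous allele-2 (dosage 2)

Quality control mirrors common SNP-array practice for autosomal analyses:
unplaced SNPs are dropped first, then sex-chromosome SNPs, then SNPs whose
missing-genotype rate exceeds the threshold (strictly greater than; a SNP at
exactly the threshold is retained). Samples are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PanelFormatError

#: Sentinel for a missing genotype call. Never a valid allele-2 dosage.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = bytes([0x01])

# two-bit PLINK code -> dosage, index = code
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# dosage (+1 so MISSING maps to index 0) -> two-bit code
_DOSAGE_TO_CODE = np.array([1, 0, 2, 3], dtype=np.uint8)

#: Chromosome labels treated as "unplaced" by default.
UNPLACED_CHROMS = frozenset({"0", ""})
#: Sex-chromosome labels dropped by default.
SEX_CHROMS = frozenset({"X", "Y"})


@dataclass(frozen=True)
class SNPRecord:
    """One SNP of the map: identifier, chromosome, 1-based bp position, alleles."""

    snp_id: str
    chrom: str
    pos_bp: int
    a1: str = "A"
    a2: str = "B"


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix plus SNP map and breed labels.

    ``snps`` is a DataFrame with columns ``snp_id, chrom, pos_bp, a1, a2`` in
    map order; ``genotypes`` is int8 with entries in {0, 1, 2, MISSING}.
    """

    snps: pd.DataFrame
    samples: list[str]
    breed_of: dict[str, str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise PanelFormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise PanelFormatError("duplicate sample ids in panel")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()].iloc[0]
            raise PanelFormatError(f"duplicate SNP id {dup!r}")
        missing_breed = [s for s in self.samples if s not in self.breed_of]
        if missing_breed:
            raise PanelFormatError(
                f"samples without breed label: {missing_breed[:5]}"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise PanelFormatError("genotype codes outside {0,1,2,MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.breed_of[s], None)
        return list(seen)

    def breed_sample_indices(self, breed: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.breed_of[s] == breed]
        return np.asarray(idx, dtype=np.intp)

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing genotype calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return (self.genotypes == MISSING).mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            snps=self.snps.loc[keep].reset_index(drop=True),
            samples=list(self.samples),
            breed_of=dict(self.breed_of),
            genotypes=self.genotypes[:, keep],
        )


@dataclass
class QCReport:
    """Bookkeeping for SNP filtering; removals apply in a fixed, disjoint order."""

    n_snps_in: int
    n_removed_unplaced: int
    n_removed_sex: int
    n_removed_missingness: int
    n_snps_out: int
    max_missing_rate: float

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_unplaced + self.n_removed_sex + self.n_removed_missingness
        )
        if self.n_snps_out != self.n_snps_in - removed:
            raise PanelFormatError("QCReport counts do not reconcile")


def apply_qc(
    panel: GenotypePanel,
    max_missing: float = 0.10,
    drop_chroms: frozenset[str] | set[str] = SEX_CHROMS,
    drop_unplaced: bool = True,
) -> tuple[GenotypePanel, QCReport]:
    """Filter SNPs: unplaced, then sex chromosomes, then missingness > ``max_missing``.

    The missingness comparison is strict: a SNP at exactly ``max_missing`` is
    retained. Samples are never removed. Returns the filtered panel and a
    :class:`QCReport`; removing every SNP is legal and yields an empty panel.
    """
    if panel.n_snps == 0:
        raise PanelFormatError("apply_qc requires a nonempty panel")
    chrom = panel.snps["chrom"].astype(str).to_numpy()
    keep = np.ones(panel.n_snps, dtype=bool)

    if drop_unplaced:
        unplaced = np.isin(chrom, list(UNPLACED_CHROMS))
    else:
        unplaced = np.zeros(panel.n_snps, dtype=bool)
    n_unplaced = int(unplaced.sum())
    keep &= ~unplaced

    sex = np.isin(chrom, list(drop_chroms)) & keep
    n_sex = int(sex.sum())
    keep &= ~sex

    rate = panel.missing_rate()
    too_missing = (rate > max_missing) & keep
    n_missing = int(too_missing.sum())
    keep &= ~too_missing

    out = panel.subset_snps(np.flatnonzero(keep))
    report = QCReport(
        n_snps_in=panel.n_snps,
        n_removed_unplaced=n_unplaced,
        n_removed_sex=n_sex,
        n_removed_missingness=n_missing,
        n_snps_out=out.n_snps,
        max_missing_rate=max_missing,
    )
    return out, report


# ---------------------------------------------------------------------------
# PLINK triplet I/O


def _read_bim(bim_path: str | Path) -> pd.DataFrame:
    if Path(bim_path).stat().st_size == 0:
        return pd.DataFrame(
            {
                "snp_id": pd.Series(dtype=str),
                "chrom": pd.Series(dtype=str),
                "pos_bp": pd.Series(dtype=np.int64),
                "a1": pd.Series(dtype=str),
                "a2": pd.Series(dtype=str),
            }
        )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    if bim.empty:
        return pd.DataFrame(columns=["snp_id", "chrom", "pos_bp", "a1", "a2"])
    return bim[["snp_id", "chrom", "pos_bp", "a1", "a2"]]


def _read_fam(fam_path: str | Path) -> list[str]:
    samples: list[str] = []
    with open(fam_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                samples.append(parts[1])
    return samples


def read_breed_table(path: str | Path, header: bool = False) -> dict[str, str]:
    """Two-column TSV mapping sample id -> breed label."""
    df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    df.columns = ["sample_id", "breed"] + list(df.columns[2:])
    return dict(zip(df["sample_id"], df["breed"]))


def decode_bed(raw: bytes, n_samples: int, n_snps: int) -> np.ndarray:
    """Unpack PLINK v1.00 SNP-major bed bytes into an (n_samples, n_snps) dosage matrix."""
    if raw[:2] != _BED_MAGIC:
        raise PanelFormatError("not a PLINK bed file (magic bytes absent)")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise PanelFormatError("only SNP-major (mode 1) bed files are supported")
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_snps:
        raise PanelFormatError(
            f"bed payload is {body.size} bytes; expected "
            f"{bytes_per_snp * n_snps} for {n_samples} samples x {n_snps} SNPs"
        )
    if n_snps == 0:
        return np.zeros((n_samples, 0), dtype=np.int8)
    body = body.reshape(n_snps, bytes_per_snp)
    # expand each byte into 4 two-bit codes, sample index little-endian
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    return _CODE_TO_DOSAGE[codes].T.copy()


def encode_bed(genotypes: np.ndarray) -> bytes:
    """Pack a dosage matrix into PLINK v1.00 SNP-major bed bytes (inverse of decode_bed)."""
    n_samples, n_snps = genotypes.shape
    if n_snps == 0:
        return _BED_MAGIC + _BED_SNP_MAJOR
    codes = _DOSAGE_TO_CODE[genotypes.T.astype(np.int64) + 1]  # (n_snps, n_samples)
    pad = (-n_samples) % 4
    if pad:
        # pad bits are zero, matching PLINK's convention
        codes = np.concatenate(
            [codes, np.zeros((n_snps, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(n_snps, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2, dtype=np.uint8)
    return _BED_MAGIC + _BED_SNP_MAJOR + packed.tobytes()


def read_panel(
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
    breed_table_path: str | Path,
    breed_table_header: bool = False,
) -> GenotypePanel:
    """Read a PLINK triplet plus breed table into a :class:`GenotypePanel`.

    SNP order follows the bim file; sample order follows the fam file. Every
    fam sample must appear in the breed table.
    """
    snps = _read_bim(bim_path)
    samples = _read_fam(fam_path)
    breed_of = read_breed_table(breed_table_path, header=breed_table_header)
    unlabeled = [s for s in samples if s not in breed_of]
    if unlabeled:
        raise PanelFormatError(
            f"samples absent from breed table: {unlabeled[:5]}"
        )
    raw = Path(bed_path).read_bytes()
    genotypes = decode_bed(raw, n_samples=len(samples), n_snps=len(snps))
    return GenotypePanel(
        snps=snps,
        samples=samples,
        breed_of={s: breed_of[s] for s in samples},
        genotypes=genotypes,
    )


def write_panel(
    panel: GenotypePanel, out_prefix: str | Path, breed_table: bool = True
) -> dict[str, Path]:
    """Write ``<prefix>.bed/.bim/.fam`` (and ``<prefix>.breeds.tsv``); round-trips exactly."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": prefix.with_suffix(".bed"),
        "bim": prefix.with_suffix(".bim"),
        "fam": prefix.with_suffix(".fam"),
    }
    paths["bed"].write_bytes(encode_bed(panel.genotypes))
    with open(paths["bim"], "w") as fh:
        for row in panel.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\t{row.a1}\t{row.a2}\n")
    with open(paths["fam"], "w") as fh:
        for s in panel.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    if breed_table:
        paths["breeds"] = prefix.parent / (prefix.name + ".breeds.tsv")
        with open(paths["breeds"], "w") as fh:
            for s in panel.samples:
                fh.write(f"{s}\t{panel.breed_of[s]}\n")
    return paths
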