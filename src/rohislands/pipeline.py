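"""End-to-end orchestration: ingest/simulate -> QC -> ROH -> islands -> reports.

``run_pipeline`` wires the stage functions together, writes every stage's
output as deterministic TSV/BED/JSON (fixed float formatting, fixed sort
order) plus track and PCA figures, and records a run manifest with all
parameters, the seed and input-file hashes. Re-running with an identical
config yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .islands import (
    call_islands_panel,
    classify_private,
    cross_breed_overlaps,
    intervals_to_bed,
    islands_to_frame,
    regions_to_frame,
    summarize_breeds,
)
from .loci import genes_in_islands, genotype_frequencies, hwe_exact_test, read_annotation, GenotypeCounts
from .panel import apply_qc, read_panel, write_panel
from .plotting import plot_pca, plot_tracks
from .roh import ROHParams, call_roh_panel, segments_to_frame, sroh
from .simulate import PanelDesign, simulate_panel, write_truth_tsv
from .stratification import ibs_matrix, pca_from_similarity

logger = logging.getLogger("rohislands")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; validated before any compute."""

    out_dir: str
    plink_prefix: str | None = None
    breed_table: str | None = None
    design: PanelDesign | None = None
    roh_params: ROHParams = field(default_factory=ROHParams)
    roh_method: str = "windowed"
    island_threshold: float = 0.5
    max_missing: float = 0.10
    annotation_path: str | None = None
    annotation_coords: str = "bed"
    candidate_snps: list[str] = field(default_factory=list)
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        if not 0 <= self.island_threshold < 1:
            raise ValidationError(
                f"island threshold {self.island_threshold} outside [0, 1)"
            )
        if not 0 <= self.max_missing <= 1:
            raise ValidationError(f"max_missing {self.max_missing} outside [0, 1]")
        if self.roh_method not in ("windowed", "exact"):
            raise ValidationError(f"unknown roh_method {self.roh_method!r}")
        if (self.plink_prefix is None) == (self.design is None):
            raise ValidationError(
                "provide exactly one input: a PLINK prefix or a simulation design"
            )
        if self.plink_prefix is not None:
            if self.breed_table is None:
                raise ValidationError("PLINK input requires a breed table")
            for ext in (".bed", ".bim", ".fam"):
                p = Path(self.plink_prefix + ext)
                if not p.exists():
                    raise ValidationError(f"input file missing: {p}")
            if not Path(self.breed_table).exists():
                raise ValidationError(f"breed table missing: {self.breed_table}")
        if self.annotation_path and not Path(self.annotation_path).exists():
            raise ValidationError(f"annotation missing: {self.annotation_path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6f")


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full analysis; returns the key in-memory results.

    Stages: load or simulate a panel, SNP QC, per-individual ROH calling,
    S_ROH summaries, per-breed islands at the sharing threshold, cross-breed
    overlap regions and private classification, candidate-locus genotype/HWE
    tables, gene intersection (if an annotation is supplied), IBS-PCA, plots
    and a JSON manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)

    manifest: dict[str, object] = {
        "package_version": __version__,
        "seed": config.seed,
        "roh_method": config.roh_method,
        "island_threshold": config.island_threshold,
        "max_missing": config.max_missing,
        "roh_params": dataclasses.asdict(config.roh_params),
        "inputs": {},
    }

    truth = None
    if config.design is not None:
        logger.info("stage simulate: generating synthetic panel")
        panel, truth = simulate_panel(config.design)
        write_panel(panel, out / "panel")
        write_truth_tsv(truth, str(out / "truth.tsv"))
        manifest["inputs"]["design"] = dataclasses.asdict(config.design)
    else:
        logger.info("stage ingest: reading PLINK triplet %s", config.plink_prefix)
        panel = read_panel(
            config.plink_prefix + ".bed",
            config.plink_prefix + ".bim",
            config.plink_prefix + ".fam",
            config.breed_table,
        )
        for ext in (".bed", ".bim", ".fam"):
            p = Path(config.plink_prefix + ext)
            manifest["inputs"][p.name] = _sha256(p)
        manifest["inputs"][Path(config.breed_table).name] = _sha256(
            Path(config.breed_table)
        )

    logger.info("stage qc: %d SNPs in", panel.n_snps)
    panel, qc_report = apply_qc(panel, max_missing=config.max_missing)
    if panel.n_snps == 0:
        logger.warning("QC removed every SNP; downstream outputs will be empty")
    (out / "qc_report.json").write_text(
        json.dumps(dataclasses.asdict(qc_report), indent=2) + "\n"
    )

    logger.info("stage roh: calling segments (%s) on %d samples", config.roh_method, panel.n_samples)
    segments = call_roh_panel(panel, config.roh_params, method=config.roh_method)
    seg_frame = segments_to_frame(segments, panel.breed_of)
    seg_frame = seg_frame.sort_values(
        ["sample_id", "chrom", "start_bp"], kind="mergesort"
    ).reset_index(drop=True)
    _write_tsv(seg_frame, out / "roh_segments.tsv")

    summary = sroh(segments, panel.samples, panel.breed_of)
    _write_tsv(
        summary.per_sample.rename_axis("sample_id").reset_index(), out / "sroh_per_sample.tsv"
    )
    _write_tsv(
        summary.per_breed.rename_axis("breed").reset_index(), out / "sroh_per_breed.tsv"
    )

    logger.info("stage islands: threshold > %s", config.island_threshold)
    islands = call_islands_panel(segments, panel, threshold=config.island_threshold)
    islands.sort(key=lambda i: (i.chrom, i.start_bp, i.breed))
    regions = cross_breed_overlaps(islands)
    counts = classify_private(islands, regions)
    isl_frame = islands_to_frame(islands)
    _write_tsv(isl_frame, out / "islands.tsv")
    intervals_to_bed(isl_frame, str(out / "islands.bed"), name_col="breed")
    reg_frame = regions_to_frame(regions)
    _write_tsv(reg_frame, out / "overlap_regions.tsv")
    intervals_to_bed(reg_frame, str(out / "overlap_regions.bed"), name_col="breeds")
    _write_tsv(counts.rename_axis("breed").reset_index(), out / "island_counts.tsv")

    genes_per_breed: dict[str, int] = {}
    if config.annotation_path:
        annotation = read_annotation(config.annotation_path, config.annotation_coords)
        gene_frame, genes_per_breed = genes_in_islands(islands, annotation)
        _write_tsv(gene_frame, out / "genes_in_islands.tsv")
    else:
        annotation = []

    breed_table = summarize_breeds(islands, summary, regions, genes_per_breed)
    _write_tsv(breed_table.reset_index(), out / "breed_summary.tsv")

    loci_rows = []
    for snp_id in config.candidate_snps:
        freq = genotype_frequencies(panel, snp_id)
        for breed, row in freq.iterrows():
            counts_obj = GenotypeCounts(
                breed=breed,
                snp_id=snp_id,
                n_hom_ref=int(row["n_hom_ref"]),
                n_het=int(row["n_het"]),
                n_hom_alt=int(row["n_hom_alt"]),
                n_missing=int(row["n_missing"]),
            )
            p = hwe_exact_test(counts_obj) if counts_obj.n_typed else float("nan")
            loci_rows.append({**row.to_dict(), "breed": breed, "hwe_p": p})
    if loci_rows:
        _write_tsv(pd.DataFrame(loci_rows), out / "candidate_loci.tsv")

    logger.info("stage pca: IBS matrix on %d samples", panel.n_samples)
    ibs = ibs_matrix(panel)
    pca = pca_from_similarity(ibs, k=3)
    coords = pd.DataFrame(
        pca.coordinates, columns=["PC1", "PC2", "PC3"], index=pca.samples
    )
    coords.insert(0, "breed", [panel.breed_of[s] for s in pca.samples])
    _write_tsv(coords.rename_axis("sample_id").reset_index(), out / "pca_coords.tsv")
    _write_tsv(
        pd.DataFrame(
            {
                "component": ["PC1", "PC2", "PC3"],
                "variance_fraction": pca.variance_fraction,
            }
        ),
        out / "pca_variance.tsv",
    )

    if config.make_plots:
        fig = plot_pca(pca, panel.breed_of)
        fig.savefig(out / "pca_pc1_pc2.png", dpi=120)
        chroms_with_islands = sorted({i.chrom for i in islands})
        for chrom in chroms_with_islands[:6]:
            pos = panel.snps.loc[panel.snps["chrom"] == chrom, "pos_bp"]
            fig = plot_tracks(
                islands, regions, annotation, chrom, (int(pos.min()), int(pos.max()))
            )
            fig.savefig(out / f"tracks_chr{chrom}.png", dpi=120)
        import matplotlib.pyplot as plt

        plt.close("all")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "panel": panel,
        "qc_report": qc_report,
        "segments": segments,
        "sroh": summary,
        "islands": islands,
        "regions": regions,
        "island_counts": counts,
        "breed_summary": breed_table,
        "pca": pca,
        "truth": truth,
    }
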