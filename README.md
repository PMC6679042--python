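# rohislands

Selection-signature analysis from SNP-array genotypes via runs of
homozygosity (ROH) and ROH islands, for population geneticists working with
multi-breed (or multi-population) panels — e.g. livestock diversity studies
on dense genotyping arrays.

## The method

A **run of homozygosity** is a contiguous stretch of homozygous genotypes in
one individual, evidence that both parental haplotypes descend from a common
ancestor (autozygosity). Segments are called per individual under PLINK-style
constraints: length ≥ 500 kb, more than 80 homozygous SNPs, at most 1
heterozygote and 2 missing calls per segment, mean density of at least one
SNP per 50 kb, and no inter-SNP gap above 100 kb. Both an overlapping-window
scanner (window of 50 SNPs, ≤ 1 heterozygote and ≤ 5 missing per window, 5%
hit threshold) and an exact reference caller are provided; the exact caller
defines the normative semantics.

Per breed, the per-SNP **incidence** f_i = (individuals whose ROH covers SNP
i) / (breed sample size) is computed, and maximal runs of SNPs with
f_i > 0.5 — regions shared by *more than half* the breed — are called **ROH
islands**, interpreted as signatures of directional selection. Islands of
different breeds overlapping by ≥ 1 bp are joined into cross-breed **overlap
regions** (connected components of the interval-overlap graph, no minimum
overlap length); islands in no region are **private** (breed-specific).
Per-individual autozygosity is summarised as S_ROH, the summed ROH length in
Mb, averaged per breed.

Supporting analyses: pairwise identity-by-state (IBS) similarity and its
principal components for panel stratification, per-breed genotype
frequencies and an exact conditional Hardy–Weinberg test at candidate loci,
and gene–island intersection against a user-supplied annotation (BED/TSV).

Because studies of this kind rarely release raw genotypes, the package
includes a first-class synthetic-panel generator: multi-breed panels with
Hardy–Weinberg background genotypes and implanted autozygous tracts (one
shared founder haplotype per tract, configurable carrier fraction per
breed), plus a truth set for end-to-end validation.

## Worked example

```python
import rohislands as ri

design = ri.PanelDesign(
    breeds=[("A", 10), ("B", 10)],
    chrom_lengths_bp={"1": 5_000_000},
    tracts=[ri.ImplantSpec("1", 1_000_000, 2_500_000, {"A": 0.8})],
    seed=1,
)
panel, truth = ri.simulate_panel(design)
segments = ri.call_roh_panel(panel, method="exact")
islands = ri.call_islands_panel(segments, panel)
for isl in islands:
    print(isl.breed, isl.chrom, isl.start_bp, isl.end_bp, round(isl.peak_incidence, 2))
```

prints

```
A 1 988375 2487874 0.8
```

one island, in breed A only: the implanted 1.0–2.5 Mb tract is recovered to
within one inter-SNP gap at each boundary (island bounds are SNP positions),
with peak incidence 0.8 = the implanted carrier fraction. Breed B, where no
tract was implanted, yields no island. `ri.cross_breed_overlaps(islands)`
returns `[]`, so `ri.classify_private(islands, [])` classifies the island
as private to A.

The same pipeline runs from the shell:

```bash
rohislands simulate --design design.yaml --out panel
rohislands islands --plink panel --breeds panel.breeds.tsv --out-prefix out
rohislands all --config pipeline.yaml   # full bundle incl. PCA, plots, manifest
```

## Layout

- `src/rohislands/panel.py` — PLINK bed/bim/fam codec, breed tables, SNP QC
- `src/rohislands/simulate.py` — synthetic panels with implanted tracts
- `src/rohislands/roh.py` — exact and windowed ROH callers, S_ROH
- `src/rohislands/islands.py` — incidence tracks, islands, overlaps, private
- `src/rohislands/loci.py` — genotype frequencies, exact HWE, gene overlap
- `src/rohislands/stratification.py` — IBS matrix, similarity PCA
- `src/rohislands/pipeline.py`, `cli.py`, `plotting.py` — orchestration

See `docs/methods.md` for modelling assumptions and numerical conventions.
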