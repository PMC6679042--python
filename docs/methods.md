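# Methods

## Genotype model and quality control

Genotypes are allele-2 dosages in {0, 1, 2} with a distinct missing sentinel
(−1), matching PLINK 1.x binary semantics (bed code `01` = missing); a
genotype is homozygous iff its dosage is 0 or 2. SNP QC applies three
filters in a fixed order so reports are reproducible: unplaced SNPs
(chromosome label "0" or empty), sex-chromosome SNPs (labels X and Y by
default), then SNPs whose missing rate is *strictly greater than* the
threshold (default 0.10 — a SNP at exactly 10% missingness is retained).
Samples are never filtered. Chromosome labels are strings throughout, so
non-numeric assemblies work unchanged.

## ROH segment rules

A called segment must satisfy, jointly:

| rule | default | comparison |
|---|---|---|
| length (bp of first→last SNP) | 500,000 | ≥ (PLINK's `--homozyg-kb` convention; `strict_gt=True` switches to the literal >) |
| homozygous SNPs (excluding het and missing) | 81 | ≥ ("more than 80") |
| heterozygotes in segment | 1 | ≤ |
| missing calls in segment | 2 | ≤ |
| mean density, length/n_snps | 50,000 bp/SNP | ≤ |
| inter-SNP gap inside segment | 100,000 bp | ≤ |

Segment length is `end_bp − start_bp` (PLINK convention, not +1).
Chromosomes are processed independently; segments never span chromosomes.

**Exact caller.** A greedy left-to-right scan forms maximal non-overlapping
candidate runs under the gap/heterozygote/missing budgets, then applies the
remaining filters. When a heterozygote (or missing call) would exceed the
budget, the current run closes at the previous SNP and a new run opens *at*
the offending SNP — i.e. a budget-consuming call attaches to the run on its
left. This tie-break is deterministic and matches scan order; it means runs
are non-overlapping even where overlapping maximal runs exist in principle.

**Windowed caller.** Mirrors PLINK's `--homozyg` overlapping-window scan:
windows of 50 consecutive SNPs are hits when they contain ≤ 1 heterozygote
and ≤ 5 missing calls; a SNP whose covering-window hit proportion is ≥ 0.05
joins a candidate run; candidate runs are then trimmed/split/filtered with
the exact caller's rules, so every emitted segment satisfies the table
above by construction. The window-level parameters are exposed in
`ROHParams` but the exact caller is the normative semantics: on
all-homozygous and single-isolated-heterozygote chromosomes the two callers
provably agree, and the tests enforce this; on heterozygote-dense inputs
the windowed scan may trim more aggressively near run edges, which is the
expected behaviour of the window approximation. Chromosomes with fewer SNPs
than one window fall back to the exact scan.

**Boundary behaviour.** A caller may extend a segment beyond a true
autozygous tract through flanking background genotypes that happen to be
homozygous (plus the one-heterozygote allowance). Per-carrier recovery is
therefore asserted as *coverage with bounded undershoot* (≤ one inter-SNP
gap per boundary); at the island level the >50% sharing requirement averages
carrier-specific overshoot away, and island boundaries are asserted to
within one inter-SNP gap of the implanted tract.

## Islands, overlaps, private classification

Incidence denominator is the full breed sample, not just ROH carriers; an
individual contributes at most 1 per SNP even if handed overlapping
segments. The island threshold is strict (> 0.5): with an even breed of
size n, exactly n/2 carriers never call an island, n/2 + 1 always do.
Islands are runs over map-contiguous SNPs and are *not* split at physical
gaps (gap control already happened at segment calling) and nearby
supra-threshold runs separated by sub-threshold SNPs are *not* merged. No
minimum island length or SNP count is imposed; a single-SNP island is valid
and flagged in the output table.

Overlap uses closed intervals on SNP positions: two islands of different
breeds overlap iff `max(starts) ≤ min(ends)` (≥ 1 shared bp; abutting
intervals do not overlap). Overlap regions are connected components of this
inter-breed graph — same-breed islands are never joined directly but can
co-occur in a component through a third breed. Region extent is reported
both as the union (min start–max end) and as intersection-like core bounds
(max start–min end), since published overlap tables vary in convention. An
island is private iff it belongs to no region, which gives the conservation
identity `n_private + |islands in regions| = n_total`, checked in tests.

BED exports convert internal 1-based inclusive `[start_bp, end_bp]` to
0-based half-open `[start_bp − 1, end_bp)`.

## Hardy–Weinberg exact test

The two-sided exact conditional test: given observed allele counts, the
heterozygote count h has probability ∝ 2^h · N! / (n_AA! h! n_BB!), and the
p-value sums all outcomes with probability ≤ the observed one. All
arithmetic is in exact rationals (`fractions.Fraction`), so the result is
exact up to the final float conversion; the test battery checks every table
with N ≤ 50 against an independently coded enumeration. p is invariant
under allele-label swap and always in (0, 1].

## IBS and PCA

Pairwise IBS is the mean over jointly non-missing SNPs of
1 − |a − b|/2; it is computed with dosage-indicator matrix products, so
cost is a few (n_samples × n_snps) matrix multiplications. A pair sharing
no typed SNP is an error naming the pair. PCA uses the classical MDS
construction on the similarity matrix: double-centre, eigendecompose, scale
eigenvectors by √λ. Negative eigenvalues — possible after centring a
similarity with missing-data noise — are dropped from the variance
normalisation, and each component's sign is fixed by making its
largest-magnitude loading positive, so plots are reproducible.

## Synthetic panels

The generator emulates a multi-breed genotyping-array study: one shared SNP
map (uniform positions per chromosome at a target spacing, default 5 kb),
per-SNP founder allele frequencies from Uniform(0.05, 0.95), per-breed
Hardy–Weinberg background genotypes, then implanted autozygous tracts, then
noise. Carriers of a tract are set homozygous for a *single shared founder
haplotype* (not independently homozygous per site), so implants behave like
true identity-by-descent segments under the density and gap rules. Carrier
count is round(fraction × n), round half up, making the >50% threshold
testable at exact boundaries. Genotype error replaces a call with a uniform
random dosage (so an error inside a tract can create a heterozygote,
exercising the ≤ 1 heterozygote allowance); missingness is applied last.
Every random block uses a sub-seed derived from (master seed, block key),
so breed blocks are independent: resizing one breed leaves the others'
genotypes unchanged.

What the generator does *not* model: linkage disequilibrium, realistic
allele-frequency spectra and breed divergence, background inbreeding, and
pedigree structure. Consequently passing recovery tests demonstrate the
correctness of the calling/threshold/overlap logic under the stated
sampling laws, not calibration on real array data; on real panels,
background autozygosity and LD will produce additional short ROH that the
segment filters are designed to handle. `expected_incidence` returns the
carrier fraction, treating background ROH coverage as zero — accurate for
these designs, since independent Hardy–Weinberg draws essentially never
produce 81 consecutive homozygous SNPs over 500 kb.

The shipped demonstration design uses 12 breeds × 30 individuals and
~20,000 SNPs on five 20-Mb chromosomes — small enough to run the whole
pipeline in seconds on one core while leaving every tract with ~400 SNPs,
comfortably above the segment thresholds — with ten 2-Mb tracts at carrier
fraction 0.8 (five private, three shared by two breeds, two by three) and
four decoys at ≤ 0.4, genotype error 0.002, missingness 0.01.

## Numerical and degenerate-input conventions

- QC on a panel whose SNPs are all removed returns an empty panel and a
  reconciling report, not an exception; an empty-SNP panel round-trips
  through the PLINK codec.
- The SNP map must be grouped by chromosome with strictly increasing
  positions; callers validate this and refuse unsorted maps.
- Pipeline TSVs are written with fixed float formatting and stable sort
  keys, so identical config + seed reproduces byte-identical tables; the
  run manifest records package version, parameters, seed and input hashes.
- CLI exit codes: 0 success, 2 validation error, 3 data-integrity error.

## Known limitations

- The windowed caller reproduces PLINK's published window semantics, but
  PLINK v1.x's internal trimming of candidate runs is under-documented;
  where behaviours could diverge, the exact caller is authoritative.
- IBS computation holds three n×m indicator matrices in memory; for panels
  beyond ~10⁴ samples a blocked implementation would be needed.
- The HWE test is exact but O(n) per table in big-rational arithmetic;
  for very large samples a log-space floating implementation would be
  preferable.
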