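"""Incidence tracks, island calling at the strict >50% threshold, overlaps."""

import itertools

import numpy as np
import pytest

from rohislands.errors import IntegrityError, ValidationError
from rohislands.islands import (
    IncidenceTrack,
    ROHIsland,
    call_islands,
    call_islands_panel,
    classify_private,
    cross_breed_overlaps,
    incidence_track,
    summarize_breeds,
)
from rohislands.roh import ROHSegment, sroh
from rohislands.simulate import ImplantSpec, PanelDesign, simulate_panel

from conftest import make_panel


def seg(sample, start, end, chrom="1"):
    return ROHSegment(sample, chrom, start, end, 10, 0, 0)


def island(breed, start, end, chrom="1"):
    return ROHIsland(breed, chrom, start, end, n_snps=5, peak_incidence=0.8)


class TestIncidenceTrack:
    def test_counting(self):
        # 10 individuals of one breed; 6 carry an ROH over SNPs 100..200 (bp 500k..1M)
        panel = make_panel(np.zeros((10, 300), dtype=np.int8))
        pos = panel.snps["pos_bp"].to_numpy()
        segments = [seg(f"s{i:03d}", pos[100], pos[200]) for i in range(6)]
        (track,) = incidence_track(segments, panel, "X")
        assert (track.fraction[100:201] == 0.6).all()
        assert (track.fraction[:100] == 0).all() and (track.fraction[201:] == 0).all()

    def test_no_segments_zero_track(self):
        panel = make_panel(np.zeros((4, 50), dtype=np.int8))
        (track,) = incidence_track([], panel, "X")
        assert (track.fraction == 0).all()

    def test_same_individual_overlapping_segments_count_once(self):
        panel = make_panel(np.zeros((5, 100), dtype=np.int8))
        pos = panel.snps["pos_bp"].to_numpy()
        segments = [seg("s000", pos[10], pos[50]), seg("s000", pos[30], pos[70])]
        (track,) = incidence_track(segments, panel, "X")
        # brute-force stab count with per-individual dedup
        brute = np.zeros(100)
        for j, p in enumerate(pos):
            covered = {
                s.sample_id
                for s in segments
                if s.start_bp <= p <= s.end_bp
            }
            brute[j] = len(covered) / 5
        assert np.array_equal(track.fraction, brute)
        assert track.fraction.max() == pytest.approx(0.2)

    def test_empty_breed_rejected(self):
        panel = make_panel(np.zeros((2, 10), dtype=np.int8))
        with pytest.raises(ValidationError, match="no samples"):
            incidence_track([], panel, "nope")


class TestCallIslands:
    def _track(self, fraction, n=10):
        fraction = np.asarray(fraction, dtype=float)
        return IncidenceTrack(
            breed="X",
            chrom="1",
            pos_bp=np.arange(1, len(fraction) + 1) * 1000,
            fraction=fraction,
            n_individuals=n,
        )

    def test_supra_threshold_run_becomes_island(self):
        f = np.zeros(50)
        f[10:20] = 0.6
        (isl,) = call_islands(self._track(f))
        assert (isl.start_bp, isl.end_bp, isl.n_snps) == (11_000, 20_000, 10)
        assert isl.peak_incidence == pytest.approx(0.6)

    def test_exactly_half_is_not_an_island(self):
        f = np.full(30, 0.5)
        assert call_islands(self._track(f)) == []

    @pytest.mark.parametrize("n", [4, 10, 20])
    def test_threshold_strictness_at_breed_size(self, n):
        """n/2 carriers give no island; one extra carrier gives exactly one."""
        panel = make_panel(np.zeros((n, 300), dtype=np.int8))
        pos = panel.snps["pos_bp"].to_numpy()
        half = [seg(f"s{i:03d}", pos[100], pos[200]) for i in range(n // 2)]
        assert call_islands_panel(half, panel) == []
        plus_one = half + [seg(f"s{n // 2:03d}", pos[100], pos[200])]
        islands = call_islands_panel(plus_one, panel)
        assert len(islands) == 1
        assert (islands[0].start_bp, islands[0].end_bp) == (pos[100], pos[200])

    def test_single_snp_island_allowed(self):
        f = np.zeros(20)
        f[7] = 0.9
        (isl,) = call_islands(self._track(f))
        assert isl.n_snps == 1 and isl.start_bp == isl.end_bp


class TestCrossBreedOverlaps:
    def test_pairwise_overlap(self):
        a = island("A", 148_400_000, 148_600_000)
        b = island("B", 148_440_000, 148_520_000)
        (region,) = cross_breed_overlaps([a, b])
        assert region.member_breeds == ("A", "B")
        assert (region.start_bp, region.end_bp) == (148_400_000, 148_600_000)
        assert (region.core_start_bp, region.core_end_bp) == (148_440_000, 148_520_000)

    def test_abutting_intervals_do_not_overlap(self):
        a = island("A", 100, 200)
        b = island("B", 201, 300)
        assert cross_breed_overlaps([a, b]) == []

    def test_shared_single_bp_overlaps(self):
        a = island("A", 100, 200)
        b = island("B", 200, 300)
        (region,) = cross_breed_overlaps([a, b])
        assert region.member_breeds == ("A", "B")

    def test_same_breed_never_joined_directly(self):
        a1 = island("A", 100, 200)
        a2 = island("A", 150, 250)
        assert cross_breed_overlaps([a1, a2]) == []

    def test_transitive_chain_single_region(self):
        a = island("A", 100, 200)
        b = island("B", 180, 400)
        c = island("C", 350, 500)  # overlaps B only
        (region,) = cross_breed_overlaps([a, b, c])
        assert region.member_breeds == ("A", "B", "C")
        assert (region.start_bp, region.end_bp) == (100, 500)

    def test_different_chromosomes_never_overlap(self):
        a = island("A", 100, 200, chrom="1")
        b = island("B", 100, 200, chrom="2")
        assert cross_breed_overlaps([a, b]) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_components_match_exhaustive_oracle(self, seed):
        """Sweep-based components equal brute-force pairwise-edge components."""
        rng = np.random.default_rng(seed)
        islands = []
        for i in range(int(rng.integers(2, 25))):
            start = int(rng.integers(0, 5_000))
            islands.append(
                island(
                    f"B{int(rng.integers(0, 5))}",
                    start,
                    start + int(rng.integers(1, 2_000)),
                    chrom=str(rng.integers(1, 3)),
                )
            )
        regions = cross_breed_overlaps(islands)
        # oracle: exhaustive pair enumeration + BFS over the edge list
        edges = {
            frozenset((i, j))
            for i, j in itertools.combinations(range(len(islands)), 2)
            if islands[i].chrom == islands[j].chrom
            and islands[i].breed != islands[j].breed
            and max(islands[i].start_bp, islands[j].start_bp)
            <= min(islands[i].end_bp, islands[j].end_bp)
        }
        adj = {i: set() for i in range(len(islands))}
        for e in edges:
            i, j = tuple(e)
            adj[i].add(j)
            adj[j].add(i)
        seen, components = set(), []
        for i in range(len(islands)):
            if i in seen or not adj[i]:
                continue
            queue, comp = [i], set()
            while queue:
                k = queue.pop()
                if k in comp:
                    continue
                comp.add(k)
                queue.extend(adj[k] - comp)
            seen |= comp
            components.append(frozenset(comp))
        expected = {
            frozenset(islands[i] for i in comp) for comp in components
        }
        got = {frozenset(r.member_islands) for r in regions}
        assert got == expected


class TestClassifyPrivate:
    def test_basic_counts(self):
        a = island("A", 100, 200)
        b = island("B", 150, 250)
        c = island("C", 10_000, 20_000)
        regions = cross_breed_overlaps([a, b, c])
        counts = classify_private([a, b, c], regions)
        assert counts.loc["TOTAL", "n_islands"] == 3
        assert counts.loc["TOTAL", "n_private"] == 1
        assert counts.loc["C", "n_private"] == 1

    def test_no_overlaps_all_private(self):
        islands = [island("A", 0, 10), island("B", 100, 110)]
        counts = classify_private(islands, [])
        assert counts.loc["TOTAL", "n_private"] == 2

    def test_region_with_foreign_island_rejected(self):
        a = island("A", 100, 200)
        b = island("B", 150, 250)
        regions = cross_breed_overlaps([a, b])
        with pytest.raises(IntegrityError):
            classify_private([a], regions)

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        islands = []
        for i in range(int(rng.integers(3, 30))):
            start = int(rng.integers(0, 3_000))
            islands.append(
                island(f"B{int(rng.integers(0, 4))}", start, start + int(rng.integers(1, 1_000)))
            )
        regions = cross_breed_overlaps(islands)
        counts = classify_private(islands, regions)
        in_regions = len({i for r in regions for i in r.member_islands})
        assert counts.loc["TOTAL", "n_private"] + in_regions == len(islands)


class TestPermutationInvariance:
    def test_sample_order_does_not_change_islands(self):
        design = PanelDesign(
            breeds=[("A", 8), ("B", 8)],
            chrom_lengths_bp={"1": 4_000_000},
            tracts=[ImplantSpec("1", 1_000_000, 2_200_000, {"A": 0.75, "B": 0.75})],
            seed=9,
        )
        panel, _ = simulate_panel(design)
        from rohislands.roh import call_roh_panel

        segments = call_roh_panel(panel, method="exact")
        islands = call_islands_panel(segments, panel)

        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.n_samples)
        from rohislands.panel import GenotypePanel

        shuffled = GenotypePanel(
            snps=panel.snps,
            samples=[panel.samples[i] for i in perm],
            breed_of=panel.breed_of,
            genotypes=panel.genotypes[perm],
        )
        islands2 = call_islands_panel(segments, shuffled)
        assert set(islands) == set(islands2)


class TestSummaries:
    def test_island_length_sum_and_conservation(self):
        islands = [
            island("A", 1_000_000, 1_600_000),
            island("A", 3_000_000, 4_400_000),
            island("B", 1_200_000, 1_500_000),
        ]
        regions = cross_breed_overlaps(islands)
        summary = sroh([], ["a1", "b1"], {"a1": "A", "b1": "B"})
        table = summarize_breeds(islands, summary, regions)
        assert table.loc["A", "sum_islands_mb"] == pytest.approx(2.0)
        assert table.loc["A", "n_islands"] == 2
        assert table.loc["A", "n_private"] == 1  # the 3.0-4.4 Mb island
        counts = classify_private(islands, regions)
        assert table["n_islands"].sum() == counts.loc["TOTAL", "n_islands"]

    def test_breed_with_no_islands_gets_zero_row(self):
        summary = sroh([], ["a1"], {"a1": "A"})
        table = summarize_breeds([], summary, [])
        assert table.loc["A", "n_islands"] == 0
        assert table.loc["A", "private_chroms"] == ""
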