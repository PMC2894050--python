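import numpy as np
import pytest

from l1prom.context import (
    DISTANCE_BINS,
    chromosome_distribution,
    classify_intergenic,
    distance_bin,
    find_neighbors,
    flank_composition,
    summarize_context,
)
from l1prom.io_formats import GenomicInterval
from l1prom.stats import pearson

from _oracles import neighbors_bruteforce


def _random_instance(rng, n_l1=20, n_genes=60, chrom_len=400_000, n_chroms=2):
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    l1 = []
    for i in range(n_l1):
        start = int(rng.integers(0, chrom_len - 7000))
        l1.append(
            (
                GenomicInterval(
                    chroms[int(rng.integers(n_chroms))], start, start + int(rng.integers(500, 7000)),
                    "+" if rng.integers(2) else "-",
                ),
                f"l1_{i}",
            )
        )
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_len - 20000))
        genes.append(
            (
                GenomicInterval(
                    chroms[int(rng.integers(n_chroms))], start, start + int(rng.integers(1000, 20000)),
                    "+" if rng.integers(2) else "-",
                ),
                f"g_{i}",
            )
        )
    return l1, genes


class TestDistanceBins:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0, "b0_5"), (4_999, "b0_5"), (5_000, "b5_10"), (9_999, "b5_10"),
            (10_000, "b10_20"), (20_000, "b20_50"), (49_999, "b20_50"),
            (50_000, "b50_100"), (99_999, "b50_100"), (100_000, "b50_100"),
        ],
    )
    def test_half_open_edges_with_closed_top(self, d, expected):
        assert distance_bin(d) == expected

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            distance_bin(100_001)
        with pytest.raises(ValueError):
            distance_bin(-1)

    def test_bins_partition_the_range(self):
        edges = sorted(lo for lo, _ in DISTANCE_BINS.values())
        his = sorted(hi for _, hi in DISTANCE_BINS.values())
        assert edges[0] == 0 and his[-1] == 100_000
        assert his[:-1] == edges[1:]  # no gaps, no overlaps


class TestNeighbors:
    def test_window_rule_inclusive_at_edge(self):
        l1 = [(GenomicInterval("chr1", 200_000, 206_000, "+"), "l1")]
        at_edge = [(GenomicInterval("chr1", 306_000, 310_000, "+"), "g1")]
        beyond = [(GenomicInterval("chr1", 306_001, 310_000, "+"), "g2")]
        assert len(find_neighbors(l1, at_edge, 100_000)) == 1
        assert find_neighbors(l1, beyond, 100_000) == []

    def test_orientation_and_bin(self):
        l1 = [(GenomicInterval("chr1", 50_000, 56_000, "+"), "l1")]
        gene = [(GenomicInterval("chr1", 57_000, 60_000, "-"), "g")]
        (rec,) = find_neighbors(l1, gene)
        assert rec.orientation == "antisense"
        assert rec.distance == 1_000 and rec.bin == "b0_5"
        assert rec.side == "downstream"

    def test_upstream_side_follows_l1_strand(self):
        gene = [(GenomicInterval("chr1", 10_000, 12_000, "+"), "g")]
        plus = [(GenomicInterval("chr1", 20_000, 26_000, "+"), "l1")]
        minus = [(GenomicInterval("chr1", 20_000, 26_000, "-"), "l1")]
        assert find_neighbors(plus, gene)[0].side == "upstream"
        assert find_neighbors(minus, gene)[0].side == "downstream"

    def test_matches_allpairs_bruteforce_on_random_instances(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            l1, genes = _random_instance(rng)
            got = {
                (r.l1_id, r.gene_id, r.distance, r.orientation)
                for r in find_neighbors(l1, genes, 100_000)
            }
            assert got == neighbors_bruteforce(l1, genes, 100_000)

    def test_strand_mirror_symmetry(self):
        """Mirroring all coordinates and flipping strands preserves the
        sense/antisense labels and swaps upstream/downstream."""
        rng = np.random.default_rng(99)
        l1, genes = _random_instance(rng, n_l1=10, n_genes=30, n_chroms=1)
        length = 400_000

        def mirror(iv):
            return GenomicInterval(
                iv.chrom, length - iv.end, length - iv.start,
                "-" if iv.strand == "+" else "+",
            )

        fwd = find_neighbors(l1, genes)
        rev = find_neighbors(
            [(mirror(iv), i) for iv, i in l1], [(mirror(iv), i) for iv, i in genes]
        )
        key = lambda recs: sorted((r.l1_id, r.gene_id, r.distance, r.orientation) for r in recs)
        assert key(fwd) == key(rev)
        side_f = {(r.l1_id, r.gene_id): r.side for r in fwd}
        # strand flip + coordinate mirror leaves each gene on the same element side
        assert all(side_f[(r.l1_id, r.gene_id)] == r.side for r in rev)


class TestIntergenic:
    def test_no_genes_is_intergenic(self):
        l1 = GenomicInterval("chr1", 1000, 7000, "+")
        assert classify_intergenic(l1, [])

    def test_l1_inside_gene_body_is_genic(self):
        l1 = GenomicInterval("chr1", 5000, 6000, "+")
        gene = [(GenomicInterval("chr1", 1000, 20000, "+"), "g")]
        assert not classify_intergenic(l1, gene)

    def test_partition_conserves_counts(self):
        rng = np.random.default_rng(3)
        l1, genes = _random_instance(rng)
        summary, _ = summarize_context(l1, genes, {"chr1": 400_000, "chr2": 400_000})
        assert summary.n_intergenic + summary.n_genic == len(l1)
        flags = [classify_intergenic(iv, genes) for iv, _ in l1]
        assert summary.n_intergenic == sum(flags)


class TestChromosomeDistribution:
    def test_density_arithmetic_and_zero_rows(self):
        l1 = [(GenomicInterval("chr1", i * 1000, i * 1000 + 100, "+"), f"x{i}") for i in range(10)]
        counts, density, (sizes, vec) = chromosome_distribution(
            l1, {"chr1": 10_000_000, "chrM": 16_000}
        )
        assert counts == {"chr1": 10, "chrM": 0}
        assert density["chr1"] == pytest.approx(1.0)
        assert sizes == [10_000_000, 16_000] and vec == [10, 0]

    def test_missing_chromosome_is_error(self):
        l1 = [(GenomicInterval("chrU", 0, 100, "+"), "x")]
        with pytest.raises(ValueError, match="chrU"):
            chromosome_distribution(l1, {"chr1": 1000})

    def test_length_proportional_placement_correlates(self):
        """Elements placed uniformly over concatenated chromosomes produce a
        strong size-count correlation."""
        rng = np.random.default_rng(17)
        sizes = {f"chr{i+1}": int(s) for i, s in enumerate(rng.integers(5e6, 2e8, size=19))}
        total = sum(sizes.values())
        bounds = np.cumsum([0] + list(sizes.values()))
        names = list(sizes)
        l1 = []
        for i, pos in enumerate(rng.integers(0, total - 200, size=1000)):
            c = int(np.searchsorted(bounds, pos, side="right") - 1)
            off = int(pos - bounds[c])
            off = min(off, sizes[names[c]] - 200)
            l1.append((GenomicInterval(names[c], off, off + 100, "+"), f"e{i}"))
        _, _, (x, y) = chromosome_distribution(l1, sizes)
        assert pearson(x, y).statistic > 0.9


class TestFlankComposition:
    def test_pure_at_flanks(self):
        genome = {"chr1": "A" * 5000 + "G" * 1000 + "T" * 5000}
        l1 = GenomicInterval("chr1", 5000, 6000, "+")
        comp = flank_composition(genome, l1, flank=4000)
        assert comp["at"] == 1.0 and comp["gc"] == 0.0

    def test_gc_plus_at_is_one_and_clipping(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=30_000))}
        l1 = GenomicInterval("chr1", 2_000, 9_000, "+")  # left flank clipped
        comp = flank_composition(genome, l1, flank=10_000)
        assert comp["gc"] + comp["at"] == pytest.approx(1.0)

    def test_intergenic_flanks_recover_background_at(self, small_sim):
        from pyfaidx import Fasta

        cfg, sim = small_sim
        genome = Fasta(str(sim.genome_fasta), as_raw=True, rebuild=False)
        ats = [
            flank_composition(genome, r.locus, flank=10_000)["at"]
            for r in sim.l1_truth
            if not r.near_gene
        ]
        assert len(ats) > 5
        assert np.mean(ats) == pytest.approx(cfg.intergenic_at, abs=0.02)
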