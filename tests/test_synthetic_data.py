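import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from l1prom.cpg import find_cpg_islands, gc_content, obs_exp_cpg
from l1prom.io_formats import read_fasta, read_gff3_genes, reverse_complement
from l1prom.motifs import CONSENSUS, scan_motif
from l1prom.synthetic_data import (
    ConfigError,
    SimConfig,
    generate_genome,
    generate_l1,
    generate_templates,
    largest_remainder_quota,
    point_mutate,
)

YY1 = CONSENSUS["YY1"]


def _hash_dir(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
        if p.suffix != ".fai"
    }


class TestTemplates:
    def test_invariants(self, templates):
        for name, t in templates.items():
            rich, poor = t.cpg_rich_variant, t.cpg_poor_variant
            assert gc_content(rich) > 0.65
            assert rich.count("CG") >= 16
            assert t.e2f_offset - (t.yy1_offset + len(YY1)) == 70
            # planted motifs intact in both variants
            for seq in (rich, poor):
                assert seq[t.yy1_offset : t.yy1_offset + 15] == YY1
                assert scan_motif(seq, CONSENSUS["E2F_long"], 0.0)
            assert CONSENSUS["RUNX3"] not in rich

    def test_same_seed_same_templates(self):
        a = generate_templates(SimConfig(seed=5), np.random.default_rng(5))
        b = generate_templates(SimConfig(seed=5), np.random.default_rng(5))
        assert {k: v.monomer_seq for k, v in a.items()} == {
            k: v.monomer_seq for k, v in b.items()
        }

    def test_rich_variant_forms_island_when_duplicated(self, templates):
        for t in templates.values():
            assert find_cpg_islands(t.cpg_rich_variant * 2)
            assert not find_cpg_islands(t.cpg_poor_variant * 3)

    def test_poor_differs_only_at_cpg_sites(self, templates):
        for t in templates.values():
            rich, poor = t.cpg_rich_variant, t.cpg_poor_variant
            diffs = [i for i, (a, b) in enumerate(zip(rich, poor)) if a != b]
            assert diffs
            for i in diffs:
                in_cpg = (rich[i] == "C" and rich[i + 1] == "G") or (
                    rich[i] == "G" and rich[i - 1] == "C"
                )
                assert in_cpg
                assert (rich[i], poor[i]) in {("C", "T"), ("G", "A")}


class TestGenerateL1:
    def test_zero_plan_gives_exact_consensus_everywhere(self, templates):
        rng = np.random.default_rng(0)
        seq, truth = generate_l1(templates["TF"], 4, [0.0] * 4, False, rng,
                                 background_mut_rate=0.0)
        utr = seq[: truth["utr_len"]]
        exact = [h for h in scan_motif(utr, YY1, 0.0)]
        assert len(exact) == 4
        assert truth["yy1_divergence_per_monomer"] == [0.0] * 4

    def test_single_monomer_truth(self, templates):
        rng = np.random.default_rng(1)
        _, truth = generate_l1(templates["A"], 1, [0.0], False, rng)
        assert truth["n_monomers"] == 1
        assert len(truth["yy1_divergence_per_monomer"]) == 1

    def test_monomer2_yy1_midpoint_in_planted_range(self, templates):
        rng = np.random.default_rng(2)
        for sub in ("TF", "GF", "A"):
            seq, truth = generate_l1(templates[sub], 3, [0.0] * 3, False, rng)
            utr = seq[: truth["utr_len"]]
            L = truth["monomer_len"]
            start_m2 = utr.rindex(YY1, 0, truth["utr_len"] - L)
            midpoint = start_m2 + 7.5
            assert 324 <= truth["utr_len"] - midpoint <= 341

    def test_island_flag_places_rich_monomers_and_detectable_island(self, templates):
        rng = np.random.default_rng(3)
        seq, truth = generate_l1(templates["TF"], 3, [0.0] * 3, True, rng)
        span = truth["island_span_promoter"]
        L = truth["monomer_len"]
        assert span == (0, 2 * L)  # monomers 3 and 2 of a 3-monomer array
        islands = find_cpg_islands(seq[: truth["utr_len"]])
        assert any(i.start < span[1] and span[0] < i.end for i in islands)

    def test_invalid_plans_rejected(self, templates):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            generate_l1(templates["TF"], 2, [0.0, 1.5], False, rng)
        with pytest.raises(ValueError):
            generate_l1(templates["TF"], 2, [0.0], False, rng)


class TestQuotas:
    def test_largest_remainder_sums_to_n(self):
        q = largest_remainder_quota(7, {"a": 0.5, "b": 0.3, "c": 0.2})
        assert sum(q.values()) == 7
        q = largest_remainder_quota(3, {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
        assert sorted(q.values()) == [1, 1, 1]

    def test_mutated_fraction_exact_at_half(self, tmp_path):
        cfg = SimConfig(seed=2, n_chroms=2, chrom_len=120_000, n_l1=10,
                        mutated_yy1_fraction=0.5, gene_density=0.0,
                        island_fraction=0.0, flank_window=20_000)
        sim = generate_genome(cfg, tmp_path)
        mutated = [r for r in sim.l1_truth if r.yy1_mutated]
        assert len(mutated) == 5
        for r in mutated:
            assert all(d > 0.20 for d in r.yy1_divergence_per_monomer[:2])


class TestGenome:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_chroms=3, chrom_len=150_000, n_l1=12,
                        flank_window=25_000)
        a = generate_genome(cfg, tmp_path / "a")
        b = generate_genome(cfg, tmp_path / "b")
        assert _hash_dir(a.outdir) == _hash_dir(b.outdir)

    def test_gene_density_zero_means_all_intergenic(self, tmp_path):
        cfg = SimConfig(seed=4, n_chroms=2, chrom_len=150_000, n_l1=10,
                        gene_density=0.0, flank_window=25_000)
        sim = generate_genome(cfg, tmp_path)
        assert all(not r.near_gene for r in sim.l1_truth)
        assert read_gff3_genes(sim.genes_gff3) == []

    def test_intergenic_background_at_composition(self, small_sim):
        """Background AT fraction of gene-free chromosomes ~ 0.613."""
        cfg, sim = small_sim
        records = {r.id: r.seq for r in read_fasta(sim.genome_fasta)}
        gene_chroms = {g.locus.chrom for g in sim.gene_truth}
        l1_by_chrom: dict = {}
        for r in sim.l1_truth:
            l1_by_chrom.setdefault(r.locus.chrom, []).append(r.locus)
        checked = 0
        for chrom, seq in records.items():
            if chrom in gene_chroms:
                continue
            mask = np.ones(len(seq), dtype=bool)
            for iv in l1_by_chrom.get(chrom, []):
                mask[iv.start : iv.end] = False
            bg = "".join(np.array(list(seq))[mask])
            assert len(bg) >= 100_000
            at = (bg.count("A") + bg.count("T")) / len(bg)
            assert at == pytest.approx(cfg.intergenic_at, abs=0.01)
            checked += 1
        assert checked >= 1

    def test_truth_island_spans_validate_thresholds_strand_aware(self, small_sim):
        cfg, sim = small_sim
        records = {r.id: r.seq for r in read_fasta(sim.genome_fasta)}
        n_islands = 0
        for r in sim.l1_truth:
            if not r.has_island:
                continue
            iv = r.island_span
            sub = records[iv.chrom][iv.start : iv.end]
            if r.locus.strand == "-":
                sub = reverse_complement(sub)
            assert len(sub) >= 400
            assert gc_content(sub) > 0.50
            assert obs_exp_cpg(sub) > 0.60
            n_islands += 1
        assert n_islands == round(cfg.island_fraction * cfg.n_l1)

    def test_minus_strand_elements_written_reverse_complemented(self, small_sim):
        cfg, sim = small_sim
        records = {r.id: r.seq for r in read_fasta(sim.genome_fasta)}
        minus = [r for r in sim.l1_truth if r.locus.strand == "-"]
        assert minus
        for r in minus[:5]:
            utr = records[r.utr_span.chrom][r.utr_span.start : r.utr_span.end]
            utr = reverse_complement(utr)
            # promoter-oriented UTR must contain the planted YY1 (possibly diverged)
            assert scan_motif(utr, YY1, 0.45)
            # the ATG codon sits immediately 3' of the UTR on the element strand
            seq = records[r.locus.chrom]
            assert reverse_complement(seq[r.atg_pos - 2 : r.atg_pos + 1]) == "ATG"

    def test_planted_gene_distances_and_orientations_recorded(self, small_sim):
        cfg, sim = small_sim
        assert sim.gene_truth
        loci = {r.l1_id: r.locus for r in sim.l1_truth}
        for g in sim.gene_truth:
            l1 = loci[g.l1_id]
            assert l1.gap_to(g.locus) == g.planted_distance_to_l1
            same = g.locus.strand == l1.strand
            assert (g.planted_orientation == "sense") == same

    def test_infeasible_chrom_len_raises(self, tmp_path):
        cfg = SimConfig(seed=0, n_chroms=1, chrom_len=5_000, n_l1=10,
                        gene_density=0.0)
        with pytest.raises(ConfigError):
            generate_genome(cfg, tmp_path)


def test_point_mutate_exact_count_and_protection():
    rng = np.random.default_rng(0)
    seq = "ACGT" * 50
    mut = point_mutate(seq, 20, rng)
    assert sum(a != b for a, b in zip(seq, mut)) == 20
    prot = point_mutate(seq, 20, rng, protect=((0, 100),))
    assert prot[:100] == seq[:100]
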