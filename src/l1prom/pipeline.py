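"""End-to-end orchestration: simulate -> segment -> islands -> motifs -> context -> report.

Single-threaded and fully deterministic under a fixed seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

from . import context as ctx
from . import cpg, motifs, monomers
from .io_formats import read_bed, read_chrom_sizes, read_gff3_genes, reverse_complement
from .report import ReportTables, assemble_report
from .stats import TestResult, chi2_trend, pearson
from .synthetic_data import SimConfig, SimResult, generate_genome

__all__ = ["PipelineResult", "extract_promoters", "analyze", "run_pipeline"]


@dataclass
class PipelineResult:
    promoters: list
    statuses: list
    islands_by_id: dict
    yy1_hits_by_id: dict
    e2f_hits_by_id: dict
    runx3_hits_by_id: dict
    summary: object
    neighbors: list
    tables: ReportTables
    sim: SimResult | None = None


def extract_promoters(genome_fasta, utr_bed, templates: dict[str, str],
                      params: monomers.SegmentationParams | None = None) -> list[monomers.PromoterModel]:
    """Read UTR spans, pull strand-oriented sequences, and segment each one."""
    genome = Fasta(str(genome_fasta), as_raw=True, rebuild=False)
    out = []
    for iv, l1_id in read_bed(utr_bed):
        seq = str(genome[iv.chrom][iv.start : iv.end]).upper()
        if iv.strand == "-":
            seq = reverse_complement(seq)
        out.append(monomers.build_promoter(l1_id, seq, templates, params))
    return out


def analyze(promoters, l1_loci, genes, chrom_sizes, window: int = ctx.DEFAULT_WINDOW,
            island_params: cpg.CpGIslandParams | None = None,
            max_divergence: float = motifs.DEFAULT_MAX_DIVERGENCE,
            truth: dict | None = None,
            rich_templates: dict[str, str] | None = None) -> PipelineResult:
    """Run islands, motif scans, YY1 classification and neighborhood context."""
    islands_by_id: dict[str, list] = {}
    yy1_by_id: dict[str, list] = {}
    e2f_by_id: dict[str, list] = {}
    runx3_by_id: dict[str, list] = {}
    statuses = []
    for p in promoters:
        islands_by_id[p.l1_id] = cpg.find_cpg_islands(p.utr_seq, island_params)
        spans = [(m.index, m.start, m.end) for m in p.monomers]
        yy1 = motifs.scan_motif(p.utr_seq, motifs.CONSENSUS["YY1"], max_divergence)
        yy1 = motifs.annotate_hits(yy1, spans, p.atg_pos)
        yy1_by_id[p.l1_id] = yy1
        e2f = motifs.scan_motif(p.utr_seq, motifs.CONSENSUS["E2F_long"], 0.0)
        e2f_by_id[p.l1_id] = motifs.annotate_hits(e2f, spans, p.atg_pos)
        runx3 = motifs.scan_motif(p.utr_seq, motifs.CONSENSUS["RUNX3"], 0.10)
        runx3_by_id[p.l1_id] = motifs.annotate_hits(runx3, spans, p.atg_pos)
        statuses.append(motifs.classify_yy1(p, yy1))
    summary, neighbors = ctx.summarize_context(l1_loci, genes, chrom_sizes, window)

    tests: dict[str, TestResult] = {}
    counts, density, (sizes_vec, counts_vec) = ctx.chromosome_distribution(l1_loci, chrom_sizes)
    if len(set(sizes_vec)) > 1 and len(set(counts_vec)) > 1 and len(sizes_vec) >= 3:
        tests["chrom_size_vs_count"] = pearson(sizes_vec, counts_vec)
    genic_ids = {r.l1_id for r in neighbors}
    genic_per_chrom = {c: 0 for c in chrom_sizes}
    for iv, l1_id in l1_loci:
        if l1_id in genic_ids:
            genic_per_chrom[iv.chrom] += 1
    chroms = [c for c in chrom_sizes if counts[c] > 0]
    if len(chroms) >= 2 and any(genic_per_chrom[c] for c in chroms):
        # score = chromosome rank by size (ties broken by name order)
        order = sorted(chroms, key=lambda c: (chrom_sizes[c], c))
        scores = {c: i + 1 for i, c in enumerate(order)}
        tests["genic_trend"] = chi2_trend(
            [genic_per_chrom[c] for c in chroms],
            [counts[c] for c in chroms],
            [scores[c] for c in chroms],
        )

    tables = assemble_report(
        promoters, statuses, islands_by_id, yy1_by_id, summary, neighbors,
        tests=tests, truth=truth, rich_templates=rich_templates,
    )
    return PipelineResult(
        promoters=promoters,
        statuses=statuses,
        islands_by_id=islands_by_id,
        yy1_hits_by_id=yy1_by_id,
        e2f_hits_by_id=e2f_by_id,
        runx3_hits_by_id=runx3_by_id,
        summary=summary,
        neighbors=neighbors,
        tables=tables,
    )


def run_pipeline(config: SimConfig, outdir: str | Path,
                 seg_params: monomers.SegmentationParams | None = None,
                 write_report: bool = True) -> PipelineResult:
    """Simulate a genome and run the full promoter survey on it."""
    outdir = Path(outdir)
    sim = generate_genome(config, outdir / "sim")
    templates = {name: t.monomer_seq for name, t in sim.templates.items()}
    promoters = extract_promoters(sim.genome_fasta, sim.utr_bed, templates, seg_params)
    l1_loci = read_bed(sim.l1_bed)
    genes = read_gff3_genes(sim.genes_gff3)
    sizes = read_chrom_sizes(sim.chrom_sizes)
    with open(sim.truth_json) as fh:
        truth = json.load(fh)
    result = analyze(
        promoters, l1_loci, genes, sizes, window=config.flank_window, truth=truth,
        rich_templates={n: t.cpg_rich_variant for n, t in sim.templates.items()},
    )
    result.sim = sim
    if write_report:
        result.tables.write(outdir / "report")
    return result
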