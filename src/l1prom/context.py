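"""Gene-neighborhood context of L1 loci.

Relates each L1 element to annotated genes within a 100-kb window on either
side: sense/antisense orientation (relative to the element's own strand),
edge-to-edge distance binned as 0-5 / 5-10 / 10-20 / 20-50 / 50-100 kb,
intergenic versus genic classification, per-chromosome counts and densities,
and flanking-sequence base composition.
"""
from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .cpg import gc_content
from .io_formats import GenomicInterval

__all__ = [
    "NeighborRecord",
    "ContextSummary",
    "DISTANCE_BINS",
    "find_neighbors",
    "classify_intergenic",
    "distance_bin",
    "chromosome_distribution",
    "flank_composition",
    "summarize_context",
]

DEFAULT_WINDOW = 100_000

#: Half-open distance bins in bp; the final edge is inclusive.
DISTANCE_BINS = {
    "b0_5": (0, 5_000),
    "b5_10": (5_000, 10_000),
    "b10_20": (10_000, 20_000),
    "b20_50": (20_000, 50_000),
    "b50_100": (50_000, 100_000),
}


@dataclass(frozen=True)
class NeighborRecord:
    l1_id: str
    gene_id: str
    distance: int
    orientation: str  # sense | antisense
    bin: str
    side: str  # upstream | downstream (relative to the L1's strand)


@dataclass
class ContextSummary:
    n_intergenic: int
    n_genic: int
    per_chrom: dict
    density_per_mb: dict
    n_sense: int
    n_antisense: int
    n_beyond_20kb: int


def distance_bin(distance: int) -> str:
    """Bin an L1-gene distance; bins partition [0, 100000] (upper edge closed)."""
    if distance < 0 or distance > DEFAULT_WINDOW:
        raise ValueError(f"distance {distance} outside [0, {DEFAULT_WINDOW}]")
    if distance == DEFAULT_WINDOW:
        return "b50_100"
    for name, (lo, hi) in DISTANCE_BINS.items():
        if lo <= distance < hi:
            return name
    raise AssertionError("unreachable: bins partition the range")


def _gene_trees(genes: list[tuple[GenomicInterval, str]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, gene_id in genes:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (iv, gene_id))
    return trees


def _side_of(l1: GenomicInterval, gene: GenomicInterval) -> str:
    """Upstream = the L1's 5' side; overlaps resolved by midpoint comparison."""
    gene_mid = (gene.start + gene.end) / 2
    l1_mid = (l1.start + l1.end) / 2
    left = gene_mid < l1_mid if gene_mid != l1_mid else gene.start < l1.start
    if l1.strand == "+":
        return "upstream" if left else "downstream"
    return "downstream" if left else "upstream"


def find_neighbors(l1_loci: list[tuple[GenomicInterval, str]],
                   genes: list[tuple[GenomicInterval, str]],
                   window: int = DEFAULT_WINDOW) -> list[NeighborRecord]:
    """All (L1, gene) pairs whose edge-to-edge gap is <= window (or overlap).

    Orientation is sense iff the gene's strand equals the L1's strand; side
    is relative to the L1's 5' end. Pairs on chromosomes absent from the L1
    namespace are simply never formed (interval trees are per-chromosome).
    """
    trees = _gene_trees(genes)
    out: list[NeighborRecord] = []
    for l1, l1_id in l1_loci:
        tree = trees.get(l1.chrom)
        if tree is None:
            continue
        # query 1 bp wider than the window: the tree is half-open, and a gap
        # of exactly `window` must still qualify (inclusive edge)
        for hit in sorted(tree.overlap(l1.start - window - 1, l1.end + window + 1)):
            gene, gene_id = hit.data
            gap = l1.gap_to(gene)
            if gap > window:
                continue
            out.append(
                NeighborRecord(
                    l1_id=l1_id,
                    gene_id=gene_id,
                    distance=gap,
                    orientation="sense" if gene.strand == l1.strand else "antisense",
                    bin=distance_bin(gap) if window <= DEFAULT_WINDOW else distance_bin(min(gap, DEFAULT_WINDOW)),
                    side=_side_of(l1, gene),
                )
            )
    return out


def classify_intergenic(l1: GenomicInterval, genes: list[tuple[GenomicInterval, str]],
                        window: int = DEFAULT_WINDOW) -> bool:
    """True iff the L1 overlaps no gene body and no gene lies within window bp."""
    for gene, _ in genes:
        if gene.chrom != l1.chrom:
            continue
        if l1.gap_to(gene) <= window:
            return False
    return True


def chromosome_distribution(l1_loci: list[tuple[GenomicInterval, str]],
                            chrom_sizes: dict[str, int]):
    """Per-chromosome counts, densities per Mb, and (size, count) vectors.

    Chromosomes present in ``chrom_sizes`` but devoid of elements keep zero
    rows; an element on a chromosome missing from the sizes is an error.
    """
    counts = {c: 0 for c in chrom_sizes}
    for iv, _ in l1_loci:
        if iv.chrom not in counts:
            raise ValueError(f"chromosome {iv.chrom} missing from chrom.sizes")
        counts[iv.chrom] += 1
    density = {c: counts[c] / (chrom_sizes[c] / 1e6) for c in chrom_sizes}
    sizes_vec = [chrom_sizes[c] for c in chrom_sizes]
    counts_vec = [counts[c] for c in chrom_sizes]
    return counts, density, (sizes_vec, counts_vec)


def flank_composition(genome, l1: GenomicInterval, flank: int = 10_000) -> dict:
    """GC/AT fractions over the two flanks combined, excluding the L1 body.

    ``genome`` is any mapping from chromosome name to an indexable sequence
    (e.g. a ``pyfaidx.Fasta``). Flanks are clipped at chromosome ends; N
    bases are excluded, so gc + at = 1 over unambiguous bases.
    """
    chrom = genome[l1.chrom]
    left = str(chrom[max(0, l1.start - flank) : l1.start])
    right = str(chrom[l1.end : l1.end + flank])
    seq = (left + right).upper()
    gc = gc_content(seq)
    return {"gc": gc, "at": 1.0 - gc}


def summarize_context(l1_loci: list[tuple[GenomicInterval, str]],
                      genes: list[tuple[GenomicInterval, str]],
                      chrom_sizes: dict[str, int],
                      window: int = DEFAULT_WINDOW) -> tuple[ContextSummary, list[NeighborRecord]]:
    """Full neighborhood summary: partition, orientation counts, distances."""
    neighbors = find_neighbors(l1_loci, genes, window)
    genic_ids = {r.l1_id for r in neighbors}
    n_genic = sum(1 for _, l1_id in l1_loci if l1_id in genic_ids)
    counts, density, _ = chromosome_distribution(l1_loci, chrom_sizes)
    summary = ContextSummary(
        n_intergenic=len(l1_loci) - n_genic,
        n_genic=n_genic,
        per_chrom=counts,
        density_per_mb=density,
        n_sense=sum(1 for r in neighbors if r.orientation == "sense"),
        n_antisense=sum(1 for r in neighbors if r.orientation == "antisense"),
        n_beyond_20kb=sum(1 for r in neighbors if r.distance > 20_000),
    )
    return summary, neighbors
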