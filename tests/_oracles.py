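"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (plain string/loop code, no numpy, no
imports from the modules under test beyond parameter containers) so that
agreement with the vectorized implementations is meaningful.
"""
from __future__ import annotations

from l1prom.cpg import CpGIslandParams

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def gc_fraction_str(sub: str) -> float:
    acgt = sum(sub.count(b) for b in "ACGT")
    return (sub.count("G") + sub.count("C")) / acgt if acgt else 0.0


def oe_str(sub: str) -> float:
    c, g = sub.count("C"), sub.count("G")
    if c == 0 or g == 0:
        return 0.0
    return sub.count("CG") * len(sub) / (c * g)


def islands_bruteforce(seq: str, params: CpGIslandParams | None = None):
    """Test every window explicitly, merge marked windows, re-validate spans."""
    params = params or CpGIslandParams()
    seq = seq.upper()
    w = params.window
    marked = []
    for i in range(0, len(seq) - w + 1, params.step):
        sub = seq[i : i + w]
        if "N" in sub:
            continue
        if gc_fraction_str(sub) > params.min_gc and oe_str(sub) > params.min_oe:
            marked.append(i)
    spans = []
    for s in marked:
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], s + w)
        else:
            spans.append([s, s + w])
    out = []
    for s, e in spans:
        if e - s <= params.min_len:
            continue
        sub = seq[s:e]
        if params.revalidate and not (
            gc_fraction_str(sub) > params.min_gc and oe_str(sub) > params.min_oe
        ):
            continue
        out.append((s, e))
    return out


def scan_bruteforce(seq: str, pattern: str, max_divergence: float):
    """Naive all-windows Hamming scan with the same overlap-resolution rule."""
    seq = seq.upper()
    L = len(pattern)
    cands = []
    for i in range(len(seq) - L + 1):
        mism = sum(
            1 for a, b in zip(seq[i : i + L], pattern) if a not in IUPAC[b]
        )
        if mism / L <= max_divergence:
            cands.append((mism / L, i))
    cands.sort()
    taken = []
    for div, i in cands:
        if any(i < e and s < i + L for s, e in taken):
            continue
        taken.append((i, i + L))
    return sorted((s, e) for s, e in taken)


def neighbors_bruteforce(l1_loci, genes, window):
    """All-pairs neighbor search with explicit gap arithmetic."""
    out = set()
    for l1, l1_id in l1_loci:
        for gene, gene_id in genes:
            if gene.chrom != l1.chrom:
                continue
            if l1.start < gene.end and gene.start < l1.end:
                gap = 0
            elif gene.end <= l1.start:
                gap = l1.start - gene.end
            else:
                gap = gene.start - l1.end
            if gap <= window:
                orientation = "sense" if gene.strand == l1.strand else "antisense"
                out.add((l1_id, gene_id, gap, orientation))
    return out
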