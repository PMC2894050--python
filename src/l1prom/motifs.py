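"""Consensus-motif scanning, YY1 integrity classification, PFMs and logos.

The scanner measures, for every window, the fraction of positions that fail
the IUPAC pattern (divergence) and reports windows at or below a divergence
cutoff. Classification of YY1 integrity uses the promoter's two ATG-proximal
("minimal promoter") monomers: a promoter is *intact* if at least one of
them carries a YY1 occurrence diverging by <= 20% from the consensus, and
*mutated* if every occurrence there diverges by more than 20%. N never
matches any pattern symbol.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CONSENSUS",
    "MotifHit",
    "YY1Status",
    "PFM",
    "scan_motif",
    "annotate_hits",
    "classify_yy1",
    "classify_active",
    "build_pfm",
    "positional_distribution",
    "modal_bin",
    "cooccurrence_with_islands",
    "plot_logo",
]

# IUPAC one-letter codes -> allowed bases (N in the subject never matches)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Consensus binding-site patterns scanned in the promoter analysis.
CONSENSUS = {
    "YY1": "GGTCGCCATCTTGGT",
    "RUNX3": "TGCATTTCCATCTGAGGTA",
    "E2F_short": "SSCGGC",
    "E2F_long": "TTTSSCGC",
}

#: Divergence above which a YY1 occurrence is considered non-functional
#: (strictly greater than 20% of pattern positions mismatching).
YY1_MUTATED_THRESHOLD = 0.20

#: Default scan cutoff, generous enough to recover degenerate occurrences.
DEFAULT_MAX_DIVERGENCE = 0.40


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    end: int
    divergence: float
    matched_seq: str
    monomer_index: int | None = None
    dist_to_atg: int | None = None


@dataclass(frozen=True)
class YY1Status:
    l1_id: str
    eligible: bool
    status: str  # intact | mutated | not_eligible
    minimal_monomer_indices: tuple[int, int] = (1, 2)
    best_divergence: float = 1.0


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix over aligned equal-length occurrences."""

    counts: np.ndarray  # 4 x L, rows A,C,G,T
    n_sequences: int
    info_bits: np.ndarray  # length L

    BASES = "ACGT"


def scan_motif(seq: str, pattern: str, max_divergence: float = DEFAULT_MAX_DIVERGENCE) -> list[MotifHit]:
    """Report every window matching an IUPAC pattern within a divergence cutoff.

    Overlapping candidate windows are resolved by keeping the lower-divergence
    hit, ties going to the leftmost. Scans the given strand only.
    """
    seq = seq.upper()
    L = len(pattern)
    n_win = len(seq) - L + 1
    if n_win < 1:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mismatch = np.zeros(n_win, dtype=np.int32)
    for j, sym in enumerate(pattern.upper()):
        allowed = np.frombuffer(IUPAC[sym].encode("ascii"), dtype=np.uint8)
        mismatch += ~np.isin(arr[j : j + n_win], allowed)
    div = mismatch / L
    candidates = np.flatnonzero(div <= max_divergence)
    # lower divergence wins; ties leftmost
    order = sorted(candidates, key=lambda i: (div[i], i))
    taken: list[tuple[int, int]] = []
    hits: list[MotifHit] = []
    name = next((k for k, v in CONSENSUS.items() if v == pattern.upper()), pattern.upper())
    for i in order:
        s, e = int(i), int(i) + L
        if any(s < te and ts < e for ts, te in taken):
            continue
        taken.append((s, e))
        hits.append(MotifHit(name, s, e, float(div[i]), seq[s:e]))
    hits.sort(key=lambda h: h.start)
    return hits


def annotate_hits(hits: list[MotifHit], monomer_spans: list[tuple[int, int, int]], atg_pos: int) -> list[MotifHit]:
    """Attach monomer indices (by full containment) and ATG distances to hits.

    ``monomer_spans`` is a list of (index, start, end) in promoter coordinates;
    ``dist_to_atg`` is ``atg_pos - hit.start`` (positive upstream of the ATG).
    """
    out = []
    for h in hits:
        idx = next(
            (i for i, s, e in monomer_spans if s <= h.start and h.end <= e), None
        )
        out.append(replace(h, monomer_index=idx, dist_to_atg=atg_pos - h.start))
    return out


def classify_yy1(promoter, hits: list[MotifHit], threshold: float = YY1_MUTATED_THRESHOLD,
                 minimal_monomers: tuple[int, int] = (1, 2)) -> YY1Status:
    """Classify a promoter's YY1 integrity over its minimal two-monomer promoter.

    Promoters with fewer than two monomers are not eligible. Among YY1 hits
    contained in the two ATG-proximal monomers, the best (lowest) divergence
    decides: <= threshold -> intact, otherwise mutated. A minimal monomer with
    no hit at all contributes divergence 1.0.
    """
    n_monomers = len(promoter.monomers)
    if n_monomers < 2:
        return YY1Status(promoter.l1_id, False, "not_eligible", minimal_monomers, 1.0)
    divs = []
    for m in minimal_monomers:
        in_m = [h.divergence for h in hits if h.monomer_index == m]
        divs.append(min(in_m) if in_m else 1.0)
    best = min(divs)
    status = "intact" if best <= threshold else "mutated"
    return YY1Status(promoter.l1_id, True, status, minimal_monomers, best)


def classify_active(promoter, yy1_status: YY1Status) -> bool:
    """A promoter is potentially active iff it has >= 2 monomers and intact YY1."""
    return len(promoter.monomers) >= 2 and yy1_status.status == "intact"


def build_pfm(hit_sequences: list[str]) -> PFM:
    """Tally a 4 x L position frequency matrix and per-column information.

    Information content uses a pseudocount of 0.25 per base:
    ``info[j] = 2 + sum_b f_bj log2 f_bj`` with f from counts + pseudocount.
    """
    if not hit_sequences:
        raise ValueError("no sequences")
    L = len(hit_sequences[0])
    if any(len(s) != L for s in hit_sequences):
        raise ValueError("all sequences must have equal length")
    counts = np.zeros((4, L), dtype=np.int64)
    index = {b: i for i, b in enumerate(PFM.BASES)}
    for s in hit_sequences:
        s = s.upper()
        for j, b in enumerate(s):
            if b not in index:
                raise ValueError(f"non-ACGT base {b!r} in motif occurrence")
            counts[index[b], j] += 1
    n = len(hit_sequences)
    freqs = (counts + 0.25) / (n + 1.0)
    info = 2.0 + (freqs * np.log2(freqs)).sum(axis=0)
    return PFM(counts=counts, n_sequences=n, info_bits=info)


def positional_distribution(hits: list[MotifHit], bin_width: int = 10) -> dict[int, int]:
    """Histogram of hit distances to the ATG in half-open bins of bin_width bp.

    Keys are bin lower edges; hits without a distance annotation are skipped.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    hist: dict[int, int] = {}
    for h in hits:
        if h.dist_to_atg is None:
            continue
        b = (h.dist_to_atg // bin_width) * bin_width
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items()))


def modal_bin(hist: dict[int, int]) -> int | None:
    """Lower edge of the most populated bin (leftmost on ties); None if empty."""
    if not hist:
        return None
    return min(hist, key=lambda b: (-hist[b], b))


def cooccurrence_with_islands(hits: list[MotifHit], islands) -> float:
    """Fraction of hits fully contained in some CpG island; 0.0 with no hits."""
    if not hits:
        return 0.0
    n_in = sum(
        1
        for h in hits
        if any(isl.start <= h.start and h.end <= isl.end for isl in islands)
    )
    return n_in / len(hits)


def plot_logo(pfm: PFM, path: str) -> None:
    """Render a minimal information-content sequence logo (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    n = pfm.n_sequences
    freqs = pfm.counts / n
    fig, ax = plt.subplots(figsize=(max(4, pfm.counts.shape[1] * 0.45), 2.4))
    for j in range(pfm.counts.shape[1]):
        heights = freqs[:, j] * pfm.info_bits[j]
        y = 0.0
        for i in np.argsort(heights):
            h = heights[i]
            if h <= 0:
                continue
            base = PFM.BASES[i]
            ax.text(
                j + 0.5, y, base, ha="center", va="bottom",
                fontsize=18, fontweight="bold", color=colors[base],
                transform=ax.transData,
                # scale glyph height to information share
                path_effects=None,
            )
            y += h
    ax.set_xlim(0, pfm.counts.shape[1] + 0.5)
    ax.set_ylim(0, 2.05)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    ax.bar(
        np.arange(pfm.counts.shape[1]) + 0.5,
        pfm.info_bits,
        width=0.9,
        color="none",
        edgecolor="0.7",
        linewidth=0.8,
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
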