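"""Segmentation of L1 5'-UTR promoters into tandem ~200-bp monomers.

The mouse L1 promoter is bipartite: a tandem array of roughly 200-bp monomer
repeats followed by a non-monomeric spacer ending at the ORF1 ATG. Monomer
copies are found by repeated local alignment of subfamily template sequences
against the UTR (masking each accepted hit), the candidates are chained into
the best non-overlapping set, and the hits are numbered 1..n starting from
the ATG-proximal copy — copy number matters because promoter activity is
additive with monomer count, and the two ATG-proximal monomers form the
minimal active promoter.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "SegmentationParams",
    "MonomerHit",
    "PromoterModel",
    "segment_monomers",
    "classify_subfamily",
    "build_promoter",
    "monomer_summary",
]

SUBFAMILY_PRIORITY = ("TF", "GF", "A", "F")


@dataclass(frozen=True)
class SegmentationParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_identity: float = 0.70
    min_len: int = 150
    max_gap: int = 50  # bp between adjacent hits of one tandem array


@dataclass(frozen=True)
class MonomerHit:
    """One monomer copy; index 1 is the ATG-proximal copy."""

    index: int
    start: int
    end: int
    template: str
    identity: float
    score: float


@dataclass
class PromoterModel:
    l1_id: str
    utr_seq: str
    atg_pos: int
    monomers: list[MonomerHit] = field(default_factory=list)
    nonmonomer_span: tuple[int, int] = (0, 0)
    subfamily: str = "unclassified"


def _make_aligner(params: SegmentationParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _alignment_identity(alignment) -> tuple[float, int, int, int]:
    """Identity over alignment columns plus the subject (target) span."""
    counts = alignment.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    t_start = int(alignment.aligned[0][0][0])
    t_end = int(alignment.aligned[0][-1][1])
    return identity, t_start, t_end, aligned_cols


def _candidate_hits(utr_seq: str, name: str, template: str, params: SegmentationParams,
                    aligner: Align.PairwiseAligner) -> list[MonomerHit]:
    """All non-overlapping local alignments of one template above threshold.

    Found by iterated best-local-alignment with hard masking of each accepted
    subject span; iteration stops at the first alignment failing the identity
    or length floor (tandem copies do not nest, so masking is lossless).
    """
    masked = list(utr_seq)
    out: list[MonomerHit] = []
    min_score = params.min_len * params.min_identity * params.match
    for _ in range(len(utr_seq) // max(1, params.min_len) + 2):
        subject = "".join(masked)
        alignments = aligner.align(subject, template)
        if not alignments or alignments.score <= 0:
            break
        best = alignments[0]
        identity, t_start, t_end, _ = _alignment_identity(best)
        if t_end - t_start < params.min_len or identity < params.min_identity:
            break
        out.append(MonomerHit(0, t_start, t_end, name, identity, float(best.score)))
        for i in range(t_start, t_end):
            masked[i] = "n"  # lower-case n never matches an ACGT template base
        if best.score < min_score:
            break
    return out


def segment_monomers(utr_seq: str, templates: dict[str, str],
                     params: SegmentationParams | None = None) -> list[MonomerHit]:
    """Segment a promoter into its monomer array.

    Candidates from all templates are chained greedily by score into a
    non-overlapping set; hits separated by more than ``max_gap`` bp are split
    into arrays and only the ATG-proximal (3'-most) array is kept. Returned
    hits are ordered 5'->3' with index 1 at the ATG-proximal end.
    """
    params = params or SegmentationParams()
    if not utr_seq:
        raise ValueError("empty UTR sequence")
    if not templates:
        raise ValueError("no templates supplied")
    aligner = _make_aligner(params)
    candidates: list[MonomerHit] = []
    for name, template in templates.items():
        candidates.extend(_candidate_hits(utr_seq, name, template.upper(), params, aligner))
    # greedy chaining: best score first, ties to the leftmost hit
    candidates.sort(key=lambda h: (-h.score, h.start))
    chosen: list[MonomerHit] = []
    for cand in candidates:
        if any(cand.start < h.end and h.start < cand.end for h in chosen):
            continue
        chosen.append(cand)
    chosen.sort(key=lambda h: h.start)
    if not chosen:
        return []
    # split into tandem arrays at gaps > max_gap; keep the 3'-most array
    arrays: list[list[MonomerHit]] = [[chosen[0]]]
    for h in chosen[1:]:
        if h.start - arrays[-1][-1].end > params.max_gap:
            arrays.append([h])
        else:
            arrays[-1].append(h)
    array = arrays[-1]
    n = len(array)
    return [
        MonomerHit(n - i, h.start, h.end, h.template, h.identity, h.score)
        for i, h in enumerate(array)
    ]


def classify_subfamily(hits: list[MonomerHit]) -> str:
    """Subfamily of the template with the highest mean identity across hits.

    Ties break by total aligned score, then by the fixed priority TF > GF > A.
    No hits -> "unclassified".
    """
    if not hits:
        return "unclassified"
    by_template: dict[str, list[MonomerHit]] = {}
    for h in hits:
        by_template.setdefault(h.template, []).append(h)
    prio = {name: i for i, name in enumerate(SUBFAMILY_PRIORITY)}

    def key(item):
        name, hs = item
        mean_id = float(np.mean([h.identity for h in hs]))
        total = sum(h.score for h in hs)
        return (-mean_id, -total, prio.get(name, len(prio)))

    return sorted(by_template.items(), key=key)[0][0]


def build_promoter(l1_id: str, utr_seq: str, templates: dict[str, str],
                   params: SegmentationParams | None = None,
                   atg_pos: int | None = None) -> PromoterModel:
    """Segment one UTR and assemble the full promoter model.

    ``atg_pos`` defaults to the UTR length (the ATG sits immediately 3' of
    the extracted UTR); the non-monomer span runs from the last monomer's end
    to the ATG.
    """
    hits = segment_monomers(utr_seq, templates, params)
    atg = len(utr_seq) if atg_pos is None else atg_pos
    last_end = hits[-1].end if hits else 0
    return PromoterModel(
        l1_id=l1_id,
        utr_seq=utr_seq,
        atg_pos=atg,
        monomers=hits,
        nonmonomer_span=(last_end, atg),
        subfamily=classify_subfamily(hits),
    )


def monomer_summary(promoters: list[PromoterModel]):
    """Per-subfamily monomer-count table: n elements, mean/sd/max count, and
    the count of elements eligible for YY1 analysis (>= 2 monomers)."""
    import pandas as pd

    rows = []
    by_sub: dict[str, list[int]] = {}
    for p in promoters:
        by_sub.setdefault(p.subfamily, []).append(len(p.monomers))
    for sub, counts in sorted(by_sub.items()):
        arr = np.asarray(counts, dtype=float)
        rows.append(
            {
                "subfamily": sub,
                "n_elements": len(counts),
                "mean_monomers": float(arr.mean()),
                "sd_monomers": float(arr.std(ddof=1)) if len(counts) > 1 else float("nan"),
                "max_monomers": int(arr.max()),
                "n_eligible": int((arr >= 2).sum()),
            }
        )
    return pd.DataFrame(rows, columns=[
        "subfamily", "n_elements", "mean_monomers", "sd_monomers", "max_monomers", "n_eligible",
    ])
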