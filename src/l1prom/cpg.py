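"""CpG-island detection and CpG-transition polymorphism counting.

Islands follow the classical sliding-window definition: spans longer than
200 bp with GC content > 50% and an observed/expected CpG ratio > 0.6, where
O/E is the Gardiner-Garden statistic N_CpG * L / (N_C * N_G). Thresholds are
strict inequalities. A window containing any N is never marked, so masked
sequence cannot seed an island.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CpGIslandParams",
    "CpGIsland",
    "TransitionSummary",
    "gc_content",
    "obs_exp_cpg",
    "find_cpg_islands",
    "cpg_transitions",
]


@dataclass(frozen=True)
class CpGIslandParams:
    window: int = 100
    step: int = 1
    min_len: int = 200
    min_gc: float = 0.50
    min_oe: float = 0.60
    revalidate: bool = True  # re-test merged spans against all thresholds

    def __post_init__(self) -> None:
        if self.window > self.min_len:
            raise ValueError("window must not exceed min_len")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class CpGIsland:
    """A called island span in promoter (or any local) coordinates."""

    start: int
    end: int
    gc: float
    obs_exp: float
    n_cpg: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TransitionSummary:
    n_positions: int
    n_mismatch: int
    n_cpg_to_tpg: int
    n_cpg_to_cpa: int

    @property
    def pct_cpg_transitions(self) -> float:
        """Fraction of mismatches that are CpG transitions (0 when no mismatch)."""
        if self.n_mismatch == 0:
            return 0.0
        return (self.n_cpg_to_tpg + self.n_cpg_to_cpa) / self.n_mismatch


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N bases are excluded from numerator and denominator."""
    seq = seq.upper()
    n_gc = seq.count("G") + seq.count("C")
    n_acgt = n_gc + seq.count("A") + seq.count("T")
    if n_acgt == 0:
        raise ValueError("gc_content undefined: no unambiguous bases")
    return n_gc / n_acgt


def obs_exp_cpg(seq: str) -> float:
    """Gardiner-Garden O/E = N_CpG * L / (N_C * N_G); 0 when C or G absent."""
    seq = seq.upper()
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (n_c * n_g)


def _base_arrays(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        cpg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_n, cpg


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return cs[w:] - cs[:-w]


def find_cpg_islands(seq: str, params: CpGIslandParams | None = None) -> list[CpGIsland]:
    """Call CpG islands with a sliding window and span-level re-validation.

    Windows of ``params.window`` advancing by ``params.step`` are marked when
    their GC fraction and O/E both strictly exceed the thresholds; marked
    windows that overlap or abut are merged, and merged spans are reported if
    longer than ``params.min_len`` and (unless ``revalidate`` is off) their
    recomputed span-level GC and O/E again pass. Returns islands sorted by
    start; spans never overlap.
    """
    params = params or CpGIslandParams()
    seq = seq.upper()
    w = params.window
    if len(seq) < w:
        return []
    is_c, is_g, is_n, cpg = _base_arrays(seq)
    c_w = _window_sums(is_c, w)
    g_w = _window_sums(is_g, w)
    n_w = _window_sums(is_n, w)
    # CpG dinucleotides fully inside the window [i, i+w): positions i..i+w-2
    cpg_w = _window_sums(cpg, w)[: len(seq) - w + 1].astype(np.int64)
    cpg_last = cpg[w - 1 :][: len(seq) - w + 1]  # dinuc starting at window's last base
    cpg_in = cpg_w - cpg_last

    gc_frac = (c_w + g_w) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c_w > 0) & (g_w > 0), cpg_in * w / (c_w * g_w), 0.0)
    marked = (gc_frac > params.min_gc) & (oe > params.min_oe) & (n_w == 0)

    starts = np.flatnonzero(marked)
    if params.step > 1:
        starts = starts[starts % params.step == 0]
    if starts.size == 0:
        return []

    spans: list[list[int]] = []
    for s in starts:
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], s + w)
        else:
            spans.append([int(s), int(s) + w])

    islands: list[CpGIsland] = []
    for start, end in spans:
        if end - start <= params.min_len:
            continue
        sub = seq[start:end]
        gc = gc_content(sub)
        oe_span = obs_exp_cpg(sub)
        if params.revalidate and not (gc > params.min_gc and oe_span > params.min_oe):
            continue
        islands.append(CpGIsland(start, end, gc, oe_span, sub.count("CG")))
    return islands


def cpg_transitions(observed: str, consensus: str) -> TransitionSummary:
    """Count CpG -> TpG / CpA transition substitutions against a consensus.

    Sequences must be pre-aligned to equal length; '-' gap columns are
    excluded from the comparison. At each consensus CpG, an observed T at the
    C position counts as CpG->TpG and an observed A at the G position as
    CpG->CpA; every other substitution contributes only to the mismatch count.
    """
    observed, consensus = observed.upper(), consensus.upper()
    if len(observed) != len(consensus):
        raise ValueError("observed and consensus must have equal (aligned) length")
    compared = n_mismatch = tpg = cpa = 0
    for i, (o, c) in enumerate(zip(observed, consensus)):
        if o == "-" or c == "-":
            continue
        compared += 1
        if o == c:
            continue
        n_mismatch += 1
        if c == "C" and i + 1 < len(consensus) and consensus[i + 1] == "G" and o == "T":
            tpg += 1
        elif c == "G" and i > 0 and consensus[i - 1] == "C" and o == "A":
            cpa += 1
    return TransitionSummary(compared, n_mismatch, tpg, cpa)
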