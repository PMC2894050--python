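"""Synthetic genomes with planted L1 promoters and ground truth.

Real surveys of mouse L1 promoters start from a curated full-length L1 set
and a reference genome. This module replaces those inputs with a generated
genome whose statistical structure matches what the downstream analysis
assumes: tandem ~200-bp monomer arrays per subfamily (TF/GF/A), a YY1
consensus and an E2F site planted at controlled divergence inside each
monomer, CpG-rich versus CpG-transition-mutated monomer variants, AT-rich
intergenic background versus GC-richer gene-dense regions, and genes planted
at controlled distances and orientations around a subset of elements. Every
planted feature is recorded in a machine-readable truth table so each
pipeline stage can be tested for exact recovery.

All randomness flows from a single seed; outputs are byte-deterministic.
Planted fractions use largest-remainder quota allocation, not Bernoulli
draws, so realized truth-table frequencies equal the configured fractions
exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import cpg
from .io_formats import (
    GenomicInterval,
    SequenceRecord,
    reverse_complement,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_gff3_genes,
)
from .motifs import CONSENSUS

__all__ = [
    "SubfamilyTemplate",
    "SimConfig",
    "L1TruthRecord",
    "GeneTruth",
    "SimResult",
    "generate_templates",
    "generate_l1",
    "generate_genome",
    "point_mutate",
    "largest_remainder_quota",
]

YY1 = CONSENSUS["YY1"]
RUNX3 = CONSENSUS["RUNX3"]

# Monomer geometry per subfamily: (length, yy1_offset, e2f_offset).
# The E2F site sits ~70 bp downstream of the YY1 15-mer in CpG-rich monomers.
_GEOMETRY = {
    "TF": (204, 100, 185),
    "GF": (208, 100, 185),
    "A": (200, 100, 185),
    "F": (206, 100, 185),
}

_BINS = [(0, 5_000), (5_000, 10_000), (10_000, 20_000), (20_000, 50_000), (50_000, 100_000)]


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass(frozen=True)
class SubfamilyTemplate:
    """One subfamily's monomer template with planted motifs and CpG variants.

    ``cpg_rich_variant`` (identical to ``monomer_seq``) is >65% GC with at
    least 16 CpG dinucleotides; ``cpg_poor_variant`` differs from it only by
    C->T / G->A transitions at CpG sites outside the planted motifs, the
    mutational signature of methyl-cytosine deamination.
    """

    name: str
    monomer_seq: str
    yy1_offset: int
    e2f_offset: int
    cpg_rich_variant: str
    cpg_poor_variant: str

    @property
    def motif_spans(self) -> list[tuple[int, int]]:
        return [
            (self.yy1_offset, self.yy1_offset + len(YY1)),
            (self.e2f_offset, self.e2f_offset + 8),
        ]

    def __len__(self) -> int:
        return len(self.monomer_seq)


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 6
    chrom_len: int = 500_000
    n_l1: int = 200
    subfamily_props: dict = field(default_factory=lambda: {"TF": 0.60, "GF": 0.08, "A": 0.32})
    monomer_count_mean: dict = field(default_factory=lambda: {"TF": 4.1, "GF": 5.6, "A": 4.26, "F": 4.0})
    mutated_yy1_fraction: float = 0.13
    island_fraction: float = 0.085
    intergenic_at: float = 0.613
    genic_gc: float = 0.40
    gene_density: float = 5.0  # genes per Mb on gene-rich chromosomes
    genic_fraction: float = 0.36  # fraction of L1s with a planted neighbor gene
    antisense_fraction: float = 0.77  # orientation mix of planted neighbor genes
    # planted neighbor-gene distance mix: most genes sit beyond 20 kb (87%)
    distance_bin_props: dict = field(default_factory=lambda: {
        "b0_5": 0.06, "b5_10": 0.04, "b10_20": 0.03, "b20_50": 0.35, "b50_100": 0.52,
    })
    flank_window: int = 100_000
    background_mut_rate: float = 0.02
    orf_stub_len: int = 300

    def __post_init__(self) -> None:
        fracs = {
            "mutated_yy1_fraction": self.mutated_yy1_fraction,
            "island_fraction": self.island_fraction,
            "intergenic_at": self.intergenic_at,
            "genic_gc": self.genic_gc,
            "genic_fraction": self.genic_fraction,
            "antisense_fraction": self.antisense_fraction,
            "background_mut_rate": self.background_mut_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.subfamily_props.values()) - 1.0) > 1e-9:
            raise ConfigError("subfamily_props must sum to 1")
        if min(self.n_chroms, self.chrom_len, self.n_l1) <= 0:
            raise ConfigError("n_chroms, chrom_len and n_l1 must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class L1TruthRecord:
    l1_id: str
    subfamily: str
    n_monomers: int
    yy1_divergence_per_monomer: list  # index 0 = ATG-proximal monomer 1
    has_island: bool
    island_span: GenomicInterval | None
    locus: GenomicInterval
    utr_span: GenomicInterval
    atg_pos: int
    near_gene: bool

    @property
    def yy1_mutated(self) -> bool:
        """True iff both minimal-promoter monomers diverge by > 20%."""
        return all(d > 0.20 for d in self.yy1_divergence_per_monomer[:2])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["locus"] = self.locus.to_dict()
        d["utr_span"] = self.utr_span.to_dict()
        d["island_span"] = self.island_span.to_dict() if self.island_span else None
        d["yy1_mutated"] = self.yy1_mutated
        return d


@dataclass
class GeneTruth:
    gene_id: str
    locus: GenomicInterval
    l1_id: str
    planted_distance_to_l1: int
    planted_orientation: str  # sense | antisense

    def to_dict(self) -> dict:
        d = asdict(self)
        d["locus"] = self.locus.to_dict()
        return d


@dataclass
class SimResult:
    outdir: Path
    genome_fasta: Path
    l1_bed: Path
    utr_bed: Path
    genes_gff3: Path
    chrom_sizes: Path
    templates_fasta: Path
    truth_json: Path
    l1_truth: list[L1TruthRecord]
    gene_truth: list[GeneTruth]
    templates: dict[str, SubfamilyTemplate]


def largest_remainder_quota(n: int, fractions: dict) -> dict:
    """Split n items over categories by largest-remainder rounding (sums to n)."""
    raw = {k: n * f for k, f in fractions.items()}
    base = {k: int(v) for k, v in raw.items()}
    left = n - sum(base.values())
    order = sorted(fractions, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:left]:
        base[k] += 1
    return base


def _draw_background(rng: np.random.Generator, length: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _random_seq(rng: np.random.Generator, length: int, at: float) -> str:
    return _draw_background(rng, length, at).tobytes().decode("ascii")


def point_mutate(seq: str, n_mut: int, rng: np.random.Generator,
                 protect: tuple[tuple[int, int], ...] = ()) -> str:
    """Substitute exactly n_mut positions (outside protected spans) at random."""
    eligible = [
        i for i in range(len(seq)) if not any(s <= i < e for s, e in protect)
    ]
    if n_mut > len(eligible):
        raise ValueError("more mutations requested than eligible positions")
    out = list(seq)
    for i in rng.choice(len(eligible), size=n_mut, replace=False):
        pos = eligible[int(i)]
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _build_rich_monomer(rng: np.random.Generator, length: int, yy1_offset: int,
                        e2f_offset: int) -> str:
    """A >65% GC monomer with >=16 CpGs, an exact YY1 and an E2F site."""
    e2f = "TTT" + "".join(rng.choice(list("GC"), size=2)) + "CGC"
    for _ in range(200):
        seq = list(_random_seq(rng, length, at=1 - 0.67))
        seq[yy1_offset : yy1_offset + len(YY1)] = YY1
        seq[e2f_offset : e2f_offset + len(e2f)] = e2f
        spans = [(yy1_offset, yy1_offset + len(YY1)), (e2f_offset, e2f_offset + len(e2f))]

        def free(i: int) -> bool:
            return not any(s <= i < e for s, e in spans)

        s = "".join(seq)
        # top up CpG dinucleotides to a comfortable margin above 16
        attempts = 0
        while s.count("CG") < 18 and attempts < 500:
            i = int(rng.integers(0, length - 1))
            if free(i) and free(i + 1):
                seq[i], seq[i + 1] = "C", "G"
                s = "".join(seq)
            attempts += 1
        # top up GC content if the draw came out low
        attempts = 0
        while cpg.gc_content(s) <= 0.655 and attempts < 500:
            i = int(rng.integers(0, length))
            if free(i) and s[i] in "AT":
                seq[i] = "G" if rng.integers(2) else "C"
                s = "".join(seq)
            attempts += 1
        if (
            cpg.gc_content(s) > 0.65
            and s.count("CG") >= 16
            and RUNX3 not in s
        ):
            return s
    raise ConfigError("could not construct a CpG-rich monomer; geometry too tight")


def _transition_mutate_cpgs(seq: str, protect: list[tuple[int, int]],
                            rng: np.random.Generator) -> str:
    """C->T or G->A at every CpG outside protected spans (deamination mimic)."""
    out = list(seq)
    i = 0
    while i < len(seq) - 1:
        if seq[i] == "C" and seq[i + 1] == "G" and not any(
            s < i + 2 and i < e for s, e in protect
        ):
            if rng.integers(2):
                out[i] = "T"  # CpG -> TpG
            else:
                out[i + 1] = "A"  # CpG -> CpA
            i += 2
        else:
            i += 1
    return "".join(out)


def generate_templates(config: SimConfig, rng: np.random.Generator) -> dict[str, SubfamilyTemplate]:
    """One monomer template per subfamily (TF, GF, A, F) with both CpG variants."""
    templates: dict[str, SubfamilyTemplate] = {}
    for name, (length, yy1_off, e2f_off) in _GEOMETRY.items():
        if e2f_off - (yy1_off + len(YY1)) != 70:
            raise ConfigError("E2F site must sit 70 bp downstream of the YY1 motif")
        if e2f_off + 8 > length:
            raise ConfigError(f"monomer of {length} bp too short for both motifs")
        rich = _build_rich_monomer(rng, length, yy1_off, e2f_off)
        spans = [(yy1_off, yy1_off + len(YY1)), (e2f_off, e2f_off + 8)]
        poor = _transition_mutate_cpgs(rich, spans, rng)
        templates[name] = SubfamilyTemplate(
            name=name,
            monomer_seq=rich,
            yy1_offset=yy1_off,
            e2f_offset=e2f_off,
            cpg_rich_variant=rich,
            cpg_poor_variant=poor,
        )
    return templates


def _mutate_yy1(monomer: str, yy1_offset: int, n_mismatch: int,
                rng: np.random.Generator) -> str:
    """Plant exactly n_mismatch substitutions inside the YY1 15-mer."""
    out = list(monomer)
    positions = rng.choice(len(YY1), size=n_mismatch, replace=False)
    for p in positions:
        pos = yy1_offset + int(p)
        alternatives = [b for b in "ACGT" if b != YY1[int(p)]]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _background_mutate(monomer: str, rate: float, protect: list[tuple[int, int]],
                       rng: np.random.Generator) -> str:
    """Sprinkle neutral substitutions, leaving motifs and CpG context intact."""
    if rate <= 0:
        return monomer
    out = list(monomer)
    n = len(monomer)
    for i in np.flatnonzero(rng.random(n) < rate):
        i = int(i)
        if any(s <= i < e for s, e in protect):
            continue
        # never touch or create a CpG: island status must survive mutation
        if out[i] == "C" and i + 1 < n and out[i + 1] == "G":
            continue
        if out[i] == "G" and i > 0 and out[i - 1] == "C":
            continue
        options = [b for b in "ACGT" if b != out[i]]
        if i + 1 < n and out[i + 1] == "G" and "C" in options:
            options.remove("C")
        if i > 0 and out[i - 1] == "C" and "G" in options:
            options.remove("G")
        out[i] = options[int(rng.integers(len(options)))]
    return "".join(out)


def generate_l1(template: SubfamilyTemplate, n_monomers: int, divergence_plan: list,
                island_flag: bool, rng: np.random.Generator,
                background_mut_rate: float = 0.02, orf_stub_len: int = 300):
    """Assemble one L1 cassette (UTR + ATG + ORF stub) plus promoter-level truth.

    The cassette is ``[monomer] * n ++ spacer ++ ATG ++ ORF stub`` with
    monomer 1 defined as the ATG-proximal copy. ``divergence_plan`` gives the
    target YY1 divergence per monomer (index 0 = monomer 1); realized values
    are quantized to fifteenths and planted inside the motif. ``island_flag``
    uses the CpG-rich variant for monomers 2 and 3 and the CpG-poor variant
    elsewhere; the spacer is sized so the monomer-2 YY1 midpoint falls 324-341
    bp upstream of the ATG. Returns (sequence, truth dict in promoter coords).
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if len(divergence_plan) != n_monomers:
        raise ValueError("divergence_plan length must equal n_monomers")
    if any(not 0 <= d <= 1 for d in divergence_plan):
        raise ValueError("divergence plan entries must be fractions in [0, 1]")
    L = len(template)
    realized: list[float] = []
    copies: list[str] = []
    for j in range(1, n_monomers + 1):  # j = ATG-proximal index
        variant = (
            template.cpg_rich_variant
            if island_flag and j in (2, 3)
            else template.cpg_poor_variant
        )
        k = int(round(divergence_plan[j - 1] * len(YY1)))
        copy = _mutate_yy1(variant, template.yy1_offset, k, rng)
        copy = _background_mutate(copy, background_mut_rate, template.motif_spans, rng)
        copies.append(copy)
        realized.append(k / len(YY1))
    # monomer n is 5'-most; monomer 1 abuts the spacer
    utr_monomers = "".join(reversed(copies))
    # place the monomer-2 YY1 midpoint 324-341 bp upstream of the ATG
    target_midpoint = int(rng.integers(332, 339))
    dist_start = target_midpoint + 8  # ATG distance of the motif's first base
    spacer_len = max(5, dist_start - 2 * L + template.yy1_offset)
    spacer = _random_seq(rng, spacer_len, at=0.61)
    utr = utr_monomers + spacer
    orf_stub = _random_seq(rng, orf_stub_len, at=0.55)
    seq = utr + "ATG" + orf_stub

    island_span = None
    if island_flag:
        hi = min(3, n_monomers)
        # promoter-coordinate span of monomers 2..3 (rich variants)
        island_span = ((n_monomers - hi) * L, (n_monomers - 1) * L)
    truth = {
        "subfamily": template.name,
        "n_monomers": n_monomers,
        "yy1_divergence_per_monomer": realized,
        "has_island": island_flag,
        "island_span_promoter": island_span,
        "utr_len": len(utr),
        "monomer_len": L,
        "spacer_len": spacer_len,
    }
    return seq, truth


def _assign_chromosomes(config: SimConfig, n_genic: int) -> tuple[list[str], list[str]]:
    """Split chromosomes into gene-rich and AT-rich intergenic groups."""
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    if n_genic == 0:
        return [], names
    if n_genic == config.n_l1:
        return names, []
    k = min(config.n_chroms - 1, max(1, round(config.n_chroms * n_genic / config.n_l1)))
    return names[:k], names[k:]


def _place_gene(l1_locus, side_left: bool, distance: int, gene_len: int,
                chrom_len: int, l1_occupied: list[tuple[int, int]]) -> tuple[int, int] | None:
    """A gene span at an exact edge distance; genes may overlap each other
    (as real annotations do) but never an L1 cassette."""
    if side_left:
        start, end = l1_locus.start - distance - gene_len, l1_locus.start - distance
    else:
        start, end = l1_locus.end + distance, l1_locus.end + distance + gene_len
    if start < 0 or end > chrom_len:
        return None
    if any(start < oe and os < end for os, oe in l1_occupied):
        return None
    return start, end


def generate_genome(config: SimConfig, outdir: str | Path) -> SimResult:
    """Write a synthetic genome, L1/gene annotations and the truth table.

    Genic L1s (quota ``genic_fraction``) live on gene-rich chromosomes with
    GC = ``genic_gc`` background and get one gene planted at a controlled
    distance bin and orientation inside ``flank_window``; intergenic L1s live
    on AT-rich chromosomes (AT = ``intergenic_at``) that carry no genes, so
    planted neighborhood labels are realized exactly. With
    ``gene_density = 0`` no genes are written at all and every element is
    intergenic. Minus-strand elements are written reverse-complemented.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    templates = generate_templates(config, rng)
    n = config.n_l1

    # --- deterministic allocation of planted attributes -------------------
    sub_quota = largest_remainder_quota(n, config.subfamily_props)
    subfamilies = [s for s, k in sorted(sub_quota.items()) for _ in range(k)]
    subfamilies = [subfamilies[i] for i in rng.permutation(n)]
    n_monomers = [
        2 + int(rng.poisson(max(0.0, config.monomer_count_mean[s] - 2)))
        for s in subfamilies
    ]
    n_mut = int(np.floor(n * config.mutated_yy1_fraction + 0.5))
    mutated = np.zeros(n, dtype=bool)
    mutated[rng.permutation(n)[:n_mut]] = True
    n_isl = int(np.floor(n * config.island_fraction + 0.5))
    eligible_isl = [i for i in range(n) if n_monomers[i] >= 3]
    if n_isl > len(eligible_isl):
        raise ConfigError(
            "island_fraction needs more elements with >= 3 monomers than were drawn"
        )
    has_island = np.zeros(n, dtype=bool)
    if n_isl:
        has_island[rng.permutation(np.array(eligible_isl))[:n_isl]] = True
    n_genic = 0 if config.gene_density == 0 else int(np.floor(n * config.genic_fraction + 0.5))
    genic = np.zeros(n, dtype=bool)
    genic[rng.permutation(n)[:n_genic]] = True
    strands = ["+" if i % 2 == 0 else "-" for i in range(n)]

    plans = []
    for i in range(n):
        if mutated[i]:
            per = [int(rng.integers(4, 7)) / 15 for _ in range(n_monomers[i])]
        else:
            per = [int(rng.integers(0, 4)) / 15 for _ in range(n_monomers[i])]
            # ATG-distal copies of intact promoters may still be degenerate
            for j in range(2, n_monomers[i]):
                per[j] = int(rng.integers(0, 7)) / 15
        plans.append(per)

    # --- build cassettes ---------------------------------------------------
    cassettes = []
    for i in range(n):
        seq, truth = generate_l1(
            templates[subfamilies[i]],
            n_monomers[i],
            plans[i],
            bool(has_island[i]),
            rng,
            background_mut_rate=config.background_mut_rate,
            orf_stub_len=config.orf_stub_len,
        )
        cassettes.append((seq, truth))

    # --- chromosome layout -------------------------------------------------
    gene_chroms, at_chroms = _assign_chromosomes(config, n_genic)
    if n_genic > 0 and not gene_chroms:
        raise ConfigError("no chromosome available for genic elements")
    if n_genic < n and not at_chroms:
        raise ConfigError("no chromosome available for intergenic elements")
    chrom_of: list[str] = []
    counters = {"genic": 0, "inter": 0}
    for i in range(n):
        if genic[i]:
            chrom_of.append(gene_chroms[counters["genic"] % len(gene_chroms)])
            counters["genic"] += 1
        else:
            chrom_of.append(at_chroms[counters["inter"] % len(at_chroms)])
            counters["inter"] += 1

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_len for c in chrom_names}
    margin = 1000
    placements: dict[int, GenomicInterval] = {}
    l1_occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for chrom in chrom_names:
        idxs = [i for i in range(n) if chrom_of[i] == chrom]
        if not idxs:
            continue
        slot = config.chrom_len // len(idxs)
        max_cassette = max(len(cassettes[i][0]) for i in idxs)
        if slot < max_cassette + 2 * margin:
            raise ConfigError(
                f"chrom_len {config.chrom_len} too small for {len(idxs)} elements on "
                f"{chrom}; increase chrom_len or n_chroms"
            )
        for k, i in enumerate(idxs):
            m = len(cassettes[i][0])
            jitter = int(rng.integers(0, slot - m - 2 * margin + 1))
            start = k * slot + margin + jitter
            placements[i] = GenomicInterval(chrom, start, start + m, strands[i])
            l1_occupied[chrom].append((start, start + m))

    # --- plant neighbor genes ----------------------------------------------
    gene_truth: list[GeneTruth] = []
    gene_records: list[tuple[GenomicInterval, str]] = []
    if n_genic:
        genic_idx = [i for i in range(n) if genic[i]]
        orient_list = ["antisense"] * int(np.floor(len(genic_idx) * config.antisense_fraction + 0.5))
        orient_list += ["sense"] * (len(genic_idx) - len(orient_list))
        orient_list = [orient_list[j] for j in rng.permutation(len(orient_list))]
        bin_names = ["b0_5", "b5_10", "b10_20", "b20_50", "b50_100"]
        usable = {
            name: (lo, min(hi, config.flank_window))
            for name, (lo, hi) in zip(bin_names, _BINS)
            if lo < config.flank_window and min(hi, config.flank_window) - lo > 1
        }
        usable_bins = list(usable.values())
        # distance-bin quota renormalized over the bins the window admits
        props = {b: config.distance_bin_props.get(b, 0.0) for b in usable}
        total_p = sum(props.values()) or 1.0
        bin_quota = largest_remainder_quota(
            len(genic_idx), {b: p / total_p for b, p in props.items()}
        )
        bin_list = [usable[b] for b, q in sorted(bin_quota.items()) for _ in range(q)]
        bin_list = [bin_list[j] for j in rng.permutation(len(bin_list))]
        for k, i in enumerate(genic_idx):
            locus = placements[i]
            lo, hi = bin_list[k]
            orientation = orient_list[k]
            gene_strand = (
                locus.strand
                if orientation == "sense"
                else ("-" if locus.strand == "+" else "+")
            )
            placed = None
            bin_choices = [(lo, hi)] + [b for b in usable_bins if b != (lo, hi)]
            for b_lo, b_hi in bin_choices:
                for attempt in range(100):
                    distance = int(rng.integers(b_lo, b_hi))
                    gene_len = int(rng.integers(2000, 8001))
                    side_left = (k + attempt) % 2 == 0
                    placed = _place_gene(
                        locus, side_left, distance, gene_len,
                        config.chrom_len, l1_occupied[locus.chrom],
                    )
                    if placed:
                        break
                if placed:
                    break
            if not placed:
                raise ConfigError(
                    "could not place a neighbor gene after bounded retries; "
                    "increase chrom_len"
                )
            gi = GenomicInterval(locus.chrom, placed[0], placed[1], gene_strand)
            gene_id = f"g{len(gene_truth) + 1:04d}"
            gene_truth.append(GeneTruth(gene_id, gi, f"l1_{i + 1:04d}", distance, orientation))
            gene_records.append((gi, gene_id))
        # background genes on gene-rich chromosomes only
        n_bg = max(
            0,
            int(round(config.gene_density * len(gene_chroms) * config.chrom_len / 1e6))
            - len(gene_truth),
        )
        for b in range(n_bg):
            chrom = gene_chroms[b % len(gene_chroms)]
            for _ in range(100):
                gene_len = int(rng.integers(2000, 8001))
                start = int(rng.integers(0, config.chrom_len - gene_len))
                if not any(start < oe and os < start + gene_len for os, oe in l1_occupied[chrom]):
                    strand = "+" if rng.integers(2) else "-"
                    gi = GenomicInterval(chrom, start, start + gene_len, strand)
                    gene_records.append((gi, f"g{len(gene_records) + 1:04d}"))
                    break

    # --- assemble chromosome sequences --------------------------------------
    chrom_seqs: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        at = 1 - config.genic_gc if chrom in gene_chroms else config.intergenic_at
        chrom_seqs[chrom] = _draw_background(rng, config.chrom_len, at)
    for i in range(n):
        locus = placements[i]
        seq = cassettes[i][0]
        if locus.strand == "-":
            seq = reverse_complement(seq)
        chrom_seqs[locus.chrom][locus.start : locus.end] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8
        )

    # --- truth records -------------------------------------------------------
    gene_ivs = [gi for gi, _ in gene_records]
    l1_truth: list[L1TruthRecord] = []
    for i in range(n):
        locus = placements[i]
        t = cassettes[i][1]
        utr_len = t["utr_len"]
        if locus.strand == "+":
            utr_span = GenomicInterval(locus.chrom, locus.start, locus.start + utr_len, "+")
            atg_pos = locus.start + utr_len
        else:
            utr_span = GenomicInterval(locus.chrom, locus.end - utr_len, locus.end, "-")
            atg_pos = locus.end - utr_len - 1
        island_span = None
        if t["island_span_promoter"] is not None:
            ps, pe = t["island_span_promoter"]
            if locus.strand == "+":
                island_span = GenomicInterval(locus.chrom, locus.start + ps, locus.start + pe, "+")
            else:
                island_span = GenomicInterval(locus.chrom, locus.end - pe, locus.end - ps, "-")
        near = any(
            gi.chrom == locus.chrom and locus.gap_to(gi) <= config.flank_window
            for gi in gene_ivs
        )
        l1_truth.append(
            L1TruthRecord(
                l1_id=f"l1_{i + 1:04d}",
                subfamily=subfamilies[i],
                n_monomers=t["n_monomers"],
                yy1_divergence_per_monomer=t["yy1_divergence_per_monomer"],
                has_island=t["has_island"],
                island_span=island_span,
                locus=locus,
                utr_span=utr_span,
                atg_pos=atg_pos,
                near_gene=near,
            )
        )

    # --- write outputs -------------------------------------------------------
    genome_fasta = outdir / "genome.fa"
    write_fasta(
        [SequenceRecord(c, chrom_seqs[c].tobytes().decode("ascii")) for c in chrom_names],
        genome_fasta,
    )
    l1_bed = outdir / "l1.bed"
    write_bed([(r.locus, r.l1_id) for r in l1_truth], l1_bed)
    utr_bed = outdir / "l1_utr.bed"
    write_bed([(r.utr_span, r.l1_id) for r in l1_truth], utr_bed)
    genes_gff3 = outdir / "genes.gff3"
    write_gff3_genes(gene_records, genes_gff3)
    chrom_sizes = outdir / "chrom.sizes"
    write_chrom_sizes(sizes, chrom_sizes)
    templates_fasta = outdir / "templates.fa"
    write_fasta(
        [SequenceRecord(t.name, t.monomer_seq) for t in templates.values()],
        templates_fasta,
    )
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(
            {
                "config": asdict(config),
                "templates": {
                    name: {
                        "monomer_seq": t.monomer_seq,
                        "yy1_offset": t.yy1_offset,
                        "e2f_offset": t.e2f_offset,
                        "cpg_rich_variant": t.cpg_rich_variant,
                        "cpg_poor_variant": t.cpg_poor_variant,
                    }
                    for name, t in templates.items()
                },
                "l1": [r.to_dict() for r in l1_truth],
                "genes": [g.to_dict() for g in gene_truth],
            },
            fh,
            indent=1,
        )
    return SimResult(
        outdir=outdir,
        genome_fasta=genome_fasta,
        l1_bed=l1_bed,
        utr_bed=utr_bed,
        genes_gff3=genes_gff3,
        chrom_sizes=chrom_sizes,
        templates_fasta=templates_fasta,
        truth_json=truth_json,
        l1_truth=l1_truth,
        gene_truth=gene_truth,
        templates=templates,
    )
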