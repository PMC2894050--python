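"""Assembly of the survey's summary tables from the pipeline stage outputs."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .context import ContextSummary, DISTANCE_BINS, NeighborRecord
from .monomers import PromoterModel, monomer_summary
from .motifs import YY1Status, MotifHit, positional_distribution, modal_bin, cooccurrence_with_islands
from .stats import percent, TestResult

__all__ = ["ReportTables", "assemble_report"]

ANALYSIS_SUBFAMILIES = ("TF", "GF", "A")  # F and unclassified are reported but excluded


@dataclass
class ReportTables:
    subfamily_table: pd.DataFrame
    yy1_table: pd.DataFrame
    island_table: pd.DataFrame
    context_table: pd.DataFrame
    cooccurrence_table: pd.DataFrame
    transition_table: pd.DataFrame | None = None
    recovery_table: pd.DataFrame | None = None
    tests: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("subfamily", "yy1", "island", "context", "cooccurrence"):
            getattr(self, f"{name}_table").to_csv(
                outdir / f"{name}_table.tsv", sep="\t", index=False
            )
        if self.transition_table is not None:
            self.transition_table.to_csv(outdir / "transition_table.tsv", sep="\t", index=False)
        if self.recovery_table is not None:
            self.recovery_table.to_csv(outdir / "recovery_table.tsv", sep="\t", index=False)
        with open(outdir / "tests.json", "w") as fh:
            json.dump(
                {
                    k: {
                        "statistic": t.statistic,
                        "df": t.df,
                        "p_value": t.p_value,
                        "test_name": t.test_name,
                    }
                    for k, t in self.tests.items()
                },
                fh,
                indent=1,
            )


def _yy1_table(promoters, statuses) -> pd.DataFrame:
    rows = []
    by_id = {p.l1_id: p for p in promoters}
    for sub in ANALYSIS_SUBFAMILIES:
        st = [s for s in statuses if by_id[s.l1_id].subfamily == sub]
        eligible = [s for s in st if s.eligible]
        mutated = [s for s in eligible if s.status == "mutated"]
        rows.append(
            {
                "subfamily": sub,
                "n_total": len(st),
                "n_eligible": len(eligible),
                "n_mutated": len(mutated),
                "n_intact": len(eligible) - len(mutated),
                "pct_mutated": percent(len(mutated), len(eligible)) if eligible else 0,
            }
        )
    return pd.DataFrame(rows)


def _island_table(promoters, islands_by_id) -> pd.DataFrame:
    rows = []
    with_island = {
        l1_id for l1_id, islands in islands_by_id.items() if islands
    }
    total = sum(
        1 for p in promoters if p.l1_id in with_island and p.subfamily in ANALYSIS_SUBFAMILIES
    )
    for sub in ANALYSIS_SUBFAMILIES:
        k = sum(1 for p in promoters if p.subfamily == sub and p.l1_id in with_island)
        rows.append(
            {
                "subfamily": sub,
                "n_islands": k,
                "pct_of_islands": percent(k, total) if total else 0,
            }
        )
    return pd.DataFrame(rows)


def _context_table(summary: ContextSummary, neighbors: list[NeighborRecord]) -> pd.DataFrame:
    n_total = summary.n_intergenic + summary.n_genic
    n_nb = len(neighbors)
    row = {
        "n_l1": n_total,
        "n_intergenic": summary.n_intergenic,
        "n_genic": summary.n_genic,
        "pct_intergenic": percent(summary.n_intergenic, n_total) if n_total else 0,
        "n_neighbor_genes": n_nb,
        "n_sense": summary.n_sense,
        "n_antisense": summary.n_antisense,
        "n_beyond_20kb": summary.n_beyond_20kb,
        "pct_beyond_20kb": percent(summary.n_beyond_20kb, n_nb) if n_nb else 0,
    }
    for name in DISTANCE_BINS:
        row[f"n_{name}"] = sum(1 for r in neighbors if r.bin == name)
    return pd.DataFrame([row])


def _cooccurrence_table(promoters, yy1_hits_by_id, islands_by_id, bin_width=10) -> pd.DataFrame:
    all_hits: list[MotifHit] = []
    fracs = []
    for p in promoters:
        hits = yy1_hits_by_id.get(p.l1_id, [])
        all_hits.extend(hits)
        if hits and islands_by_id.get(p.l1_id):
            fracs.append(cooccurrence_with_islands(hits, islands_by_id[p.l1_id]))
    hist = positional_distribution(all_hits, bin_width)
    peak = modal_bin(hist)
    island_hits = [
        h
        for p in promoters
        for h in yy1_hits_by_id.get(p.l1_id, [])
        if islands_by_id.get(p.l1_id)
    ]
    n_in = sum(
        1
        for p in promoters
        for h in yy1_hits_by_id.get(p.l1_id, [])
        if any(i.start <= h.start and h.end <= i.end for i in islands_by_id.get(p.l1_id, []))
    )
    return pd.DataFrame(
        [
            {
                "n_yy1_hits": len(all_hits),
                "modal_bin_start": peak,
                "modal_bin_end": None if peak is None else peak + bin_width,
                "n_hits_in_island_promoters": len(island_hits),
                "n_hits_inside_islands": n_in,
                "cooccurrence_island_promoters": (
                    n_in / len(island_hits) if island_hits else 0.0
                ),
            }
        ]
    )


def _recovery_table(promoters, statuses, islands_by_id, truth: dict) -> pd.DataFrame:
    truth_l1 = {r["l1_id"]: r for r in truth["l1"]}
    by_id = {p.l1_id: p for p in promoters}
    n = len(truth_l1)
    planted_mut = sum(1 for r in truth_l1.values() if r["yy1_mutated"])
    recovered_mut = sum(
        1
        for s in statuses
        if s.eligible and s.status == "mutated"
    )
    planted_isl = sum(1 for r in truth_l1.values() if r["has_island"])
    recovered_isl = sum(1 for l1_id, isl in islands_by_id.items() if isl)
    planted_counts = {}
    recovered_counts = {}
    for sub in ANALYSIS_SUBFAMILIES:
        planted_counts[sub] = sum(1 for r in truth_l1.values() if r["subfamily"] == sub)
        recovered_counts[sub] = sum(1 for p in promoters if p.subfamily == sub)
    rows = [
        {"quantity": "n_l1", "planted": n, "recovered": len(promoters)},
        {"quantity": "mutated_yy1", "planted": planted_mut, "recovered": recovered_mut},
        {"quantity": "cpg_islands", "planted": planted_isl, "recovered": recovered_isl},
    ]
    for sub in ANALYSIS_SUBFAMILIES:
        rows.append(
            {
                "quantity": f"subfamily_{sub}",
                "planted": planted_counts[sub],
                "recovered": recovered_counts[sub],
            }
        )
    mean_nm_truth = {}
    for sub in ANALYSIS_SUBFAMILIES:
        vals = [r["n_monomers"] for r in truth_l1.values() if r["subfamily"] == sub]
        rec = [len(by_id[r["l1_id"]].monomers) for r in truth_l1.values() if r["subfamily"] == sub and r["l1_id"] in by_id]
        if vals:
            rows.append(
                {
                    "quantity": f"mean_monomers_{sub}",
                    "planted": sum(vals) / len(vals),
                    "recovered": sum(rec) / len(rec) if rec else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def transition_summary_table(promoters, islands_by_id, rich_templates: dict[str, str]) -> pd.DataFrame:
    """Monomer-1 polymorphism vs the subfamily consensus, split by island status.

    Compares each promoter's ATG-proximal monomer (when its span matches the
    template length) against the CpG-rich consensus monomer and aggregates
    mismatch and CpG-transition counts for island-bearing vs island-free
    promoters.
    """
    from .cpg import cpg_transitions

    groups = {"with_island": [0, 0, 0, 0], "without_island": [0, 0, 0, 0]}
    n_monomers = {"with_island": 0, "without_island": 0}
    for p in promoters:
        rich = rich_templates.get(p.subfamily)
        if rich is None or not p.monomers:
            continue
        m1 = p.monomers[-1]
        if m1.end - m1.start != len(rich):
            continue  # indel-shifted copy: gapless comparison not meaningful
        s = cpg_transitions(p.utr_seq[m1.start : m1.end], rich)
        key = "with_island" if islands_by_id.get(p.l1_id) else "without_island"
        acc = groups[key]
        acc[0] += s.n_positions
        acc[1] += s.n_mismatch
        acc[2] += s.n_cpg_to_tpg
        acc[3] += s.n_cpg_to_cpa
        n_monomers[key] += 1
    rows = []
    for key, (pos, mism, tpg, cpa) in groups.items():
        rows.append(
            {
                "group": key,
                "n_monomers": n_monomers[key],
                "n_positions": pos,
                "n_mismatch": mism,
                "n_cpg_to_tpg": tpg,
                "n_cpg_to_cpa": cpa,
                "pct_cpg_transitions": (
                    round(100 * (tpg + cpa) / mism, 1) if mism else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def assemble_report(promoters: list[PromoterModel], statuses: list[YY1Status],
                    islands_by_id: dict, yy1_hits_by_id: dict,
                    summary: ContextSummary, neighbors: list[NeighborRecord],
                    tests: dict[str, TestResult] | None = None,
                    truth: dict | None = None,
                    rich_templates: dict[str, str] | None = None) -> ReportTables:
    """Build every summary table; append a planted-vs-recovered section when
    a truth table is supplied."""
    return ReportTables(
        subfamily_table=monomer_summary(promoters),
        yy1_table=_yy1_table(promoters, statuses),
        island_table=_island_table(promoters, islands_by_id),
        context_table=_context_table(summary, neighbors),
        cooccurrence_table=_cooccurrence_table(promoters, yy1_hits_by_id, islands_by_id),
        transition_table=(
            transition_summary_table(promoters, islands_by_id, rich_templates)
            if rich_templates
            else None
        ),
        recovery_table=_recovery_table(promoters, statuses, islands_by_id, truth) if truth else None,
        tests=tests or {},
    )
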