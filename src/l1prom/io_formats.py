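"""Coordinate types and readers/writers for FASTA, BED, GFF3 and chrom.sizes.

All internal coordinates are 0-based half-open on the forward strand;
conversion to/from 1-based formats happens only at the format boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger("l1prom")

DNA_ALPHABET = frozenset("ACGTN")
STRANDS = ("+", "-")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 for any overlap or book-ended intervals."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomicInterval":
        return cls(d["chrom"], int(d["start"]), int(d["end"]), d.get("strand", "+"))


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}, upper-cased on construction."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _find_bad_fasta_line(path: Path) -> tuple[int, str] | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(">"):
                continue
            if set(stripped.upper()) - DNA_ALPHABET:
                return lineno, stripped
    return None


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (case-normalized, N allowed).

    Raises ParseError naming the offending line for illegal characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
        except ValueError as exc:
            bad = _find_bad_fasta_line(path)
            where = f" at line {bad[0]}" if bad else ""
            raise ParseError(f"{path}{where}: {exc}") from exc
    if not records:
        # SeqIO silently yields nothing for a non-FASTA file
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path} at line 1: not a FASTA header: {first!r}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = (_BioRecord(Seq(r.seq), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3+ intervals; missing strand defaults to '+' with a warning.

    BED is natively 0-based half-open, so coordinates pass through unchanged.
    """
    out: list[tuple[GenomicInterval, str]] = []
    defaulted = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(
                    f"{path} line {lineno}: empty or inverted interval {start}-{end}"
                )
            name = cols[3] if len(cols) > 3 else f"feature_{lineno}"
            if len(cols) > 5 and cols[5] in STRANDS:
                strand = cols[5]
            else:
                strand = "+"
                defaulted += 1
            out.append((GenomicInterval(chrom, start, end, strand), name))
    if defaulted:
        logger.warning("%s: %d BED records lacked a strand; defaulted to '+'", path, defaulted)
    return out


def write_bed(records: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gff3_genes(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read rows of type 'gene' from a GFF3 file.

    GFF3 1-based inclusive spans become 0-based half-open (start-1, end).
    Rows missing an ID attribute are skipped with a logged count.
    """
    out: list[tuple[GenomicInterval, str]] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path} line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path} line {lineno}: invalid GFF3 span {start1}-{end1}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                skipped += 1
                continue
            strand = cols[6] if cols[6] in STRANDS else "+"
            out.append((GenomicInterval(cols[0], start1 - 1, end1, strand), gene_id))
    if skipped:
        logger.warning("%s: skipped %d gene rows without an ID attribute", path, skipped)
    return out


def write_gff3_genes(records: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, gene_id in records:
            fh.write(
                f"{iv.chrom}\tl1prom\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={gene_id}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column <chrom>\\t<length> TSV into an ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path} line {lineno}: expected 2 columns")
            name, length = cols[0], int(cols[1])
            if length <= 0:
                raise ParseError(f"{path} line {lineno}: non-positive length {length}")
            if name in sizes:
                raise ParseError(f"{path} line {lineno}: duplicate chromosome {name}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
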