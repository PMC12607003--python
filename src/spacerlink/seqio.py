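"""Sequence I/O and coordinate conventions shared by all pipeline stages.

All internal arithmetic is 0-based half-open; everything written to report
files is 1-based inclusive. :func:`to_one_based` / :func:`from_one_based`
are exact inverses.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NUCLEOTIDES = set("ACGTN")
#: full IUPAC nucleotide alphabet accepted on input
IUPAC_NUCLEOTIDES = set("ACGTNRYSWKMBDHV")


class FastaError(ValueError):
    """Malformed FASTA input (empty record, bad character, duplicate id)."""


@dataclass(frozen=True)
class ScaffoldRecord:
    """A nucleotide scaffold: unique id plus uppercase sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a scaffold with strand."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert 0-based half-open to 1-based inclusive coordinates."""
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert 1-based inclusive to 0-based half-open coordinates."""
    return start1 - 1, end1


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ScaffoldRecord]:
    """Read a (optionally gzipped) FASTA file into :class:`ScaffoldRecord` s.

    Sequences are uppercased and validated against the IUPAC nucleotide
    alphabet; duplicate ids and empty records are rejected.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaError(f"empty record {rec.id!r} in {path}")
            bad = set(seq) - IUPAC_NUCLEOTIDES
            if bad:
                raise FastaError(
                    f"record {rec.id!r} in {path} contains non-IUPAC "
                    f"characters: {sorted(bad)}"
                )
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(ScaffoldRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(sequence: str) -> str:
    """Reverse complement; involution on IUPAC nucleotides, N maps to N."""
    return str(Seq(sequence).reverse_complement())


def as_seqrecords(records: Iterable[ScaffoldRecord]) -> list[SeqRecord]:
    """Adapter to biopython SeqRecords (for interop / external writers)."""
    return [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
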