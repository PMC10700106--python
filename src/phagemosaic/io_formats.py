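"""Genome records, 1-based inclusive intervals, and file format plumbing.

All coordinates inside the package are 1-based inclusive (GenBank style);
conversion to 0-based half-open happens only at BED export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_INVALID_RE = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence.

    ``source`` tags provenance: "accession" for downloaded references,
    "synthetic" for simulated genomes, "unknown" otherwise.
    """

    id: str
    seq: str
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.source not in ("accession", "synthetic", "unknown"):
            raise ValueError(f"unknown source tag {self.source!r}")
        m = _INVALID_RE.search(self.seq)
        if m:
            raise ValueError(
                f"invalid base {m.group()!r} at position {m.start() + 1} "
                f"in record {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.seq[pos - 1]

    def subseq(self, start: int, end: int) -> str:
        """Subsequence over the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self.seq)):
            raise ValueError(
                f"interval {start}-{end} outside record {self.id!r} "
                f"of length {len(self.seq)}"
            )
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class GenomeInterval:
    """1-based inclusive interval on a named genome; forward strand only."""

    genome_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.genome_id == other.genome_id
            and self.start <= other.end
            and other.start <= self.end
        )

    def to_bed_fields(self) -> tuple[str, int, int, str]:
        """Convert to BED 0-based half-open (start-1, end)."""
        return (self.genome_id, self.start - 1, self.end, self.label or ".")


def interval_from_bed_fields(chrom: str, start: int, end: int, label: str = "") -> GenomeInterval:
    """Inverse of :meth:`GenomeInterval.to_bed_fields`."""
    return GenomeInterval(chrom, start + 1, end, label)


def read_fasta(path: str | Path, source: str = "unknown") -> list[GenomeRecord]:
    """Read all records from a FASTA file, uppercasing sequences.

    Raises on missing file, empty records, and non-ACGTN characters (the
    offending position is reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(rec.id, str(rec.seq).upper(), source=source))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank(path: str | Path, source: str = "accession") -> list[GenomeRecord]:
    """Read GenBank records, keeping only id and sequence (features ignored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [
        GenomeRecord(rec.id, str(rec.seq).upper(), source=source)
        for rec in SeqIO.parse(str(path), "genbank")
    ]


def write_bed(intervals: Sequence[GenomeInterval], path: str | Path) -> None:
    """Write intervals as BED3+name, converting to 0-based half-open."""
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            chrom, start, end, label = iv.to_bed_fields()
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
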