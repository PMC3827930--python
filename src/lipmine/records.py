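"""Protein records and FASTA I/O.

A :class:`ProteinRecord` is the unit every stage passes around: an
identifier, the free-text description from the FASTA header, the residue
string, and an optional mature-chain offset (number of N-terminal residues
removed as a signal peptide).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

__all__ = ["ProteinRecord", "STANDARD_AA", "read_fasta", "write_fasta"]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identifier and header description."""

    id: str
    seq: str
    description: str = ""
    mature_offset: int = 0  # residues stripped from the N-terminus, 0 = precursor

    def __post_init__(self):
        if not self.id:
            raise InputError("record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}".strip()

    def residue(self, pos: int) -> str:
        """1-based residue access."""
        if not 1 <= pos <= len(self.seq):
            raise InputError(f"position {pos} outside sequence of length {len(self.seq)}")
        return self.seq[pos - 1]

    def with_seq(self, seq: str, **changes) -> "ProteinRecord":
        return replace(self, seq=seq, **changes)


def _from_seqrecord(rec: SeqRecord) -> ProteinRecord:
    desc = rec.description
    if desc.startswith(rec.id):
        desc = desc[len(rec.id):].strip()
    return ProteinRecord(id=rec.id, seq=str(rec.seq), description=desc)


def read_fasta(source) -> list[ProteinRecord]:
    """Read protein records from a path, file handle or FASTA-format string."""
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        handle = open(source)
    else:
        handle = source
    try:
        records = [_from_seqrecord(r) for r in SeqIO.parse(handle, "fasta")]
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise InputError("no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], destination=None, width: int = 60) -> str:
    """Write records as FASTA wrapped at ``width`` columns; returns the text."""
    out = io.StringIO()
    for rec in records:
        out.write(f">{rec.header}\n")
        for i in range(0, len(rec.seq), width):
            out.write(rec.seq[i:i + width] + "\n")
    text = out.getvalue()
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)
    return text
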