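"""FASTA input/output helpers shared across the pipeline.

Thin wrappers over Biopython's SeqIO that normalize records to plain
(seq_id, uppercase sequence) tuples and support reading several files
as one merged dataset — the equivalent of concatenating per-sample
assemblies before scanning.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "read_fasta_many", "write_fasta"]


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (seq_id, uppercase sequence) from one FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq).upper()


def read_fasta_many(paths: Iterable[str | Path]) -> Iterator[tuple[str, str]]:
    """Yield records from several FASTA files as one merged stream."""
    for path in paths:
        yield from read_fasta(path)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (seq_id, sequence) tuples as single-line-description FASTA."""
    seq_records = (
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in records
    )
    SeqIO.write(seq_records, str(path), "fasta")
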