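"""FASTA reading/writing helpers (thin wrappers over Bio.SeqIO)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "reverse_complement"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into {record id: uppercase sequence}."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]
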