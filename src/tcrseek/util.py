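"""Small shared helpers: translation, complementation, FASTA/FASTQ IO."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate(nt: str) -> str:
    """Translate a nucleotide string (length must be a multiple of 3)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ (optionally gzipped) into (id, sequence) tuples."""
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fastq")]


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write reads as FASTQ with a constant dummy quality of 'I'."""
    with _open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
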