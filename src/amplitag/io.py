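"""Light I/O helpers around Biopython for the formats the toolkit consumes."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "read_fastq", "iter_fastq_pairs", "write_fastq"]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """(name, sequence) tuples from a (possibly gzipped) FASTA file."""
    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with _open(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """(name, sequence) tuples from a (possibly gzipped) FASTQ file."""
    with _open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def iter_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, r1_seq, r2_seq) from two synchronized FASTQ files."""
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for rec1, rec2 in zip(SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq")):
            rid = rec1.id.rsplit("/", 1)[0]
            yield rid, str(rec1.seq).upper(), str(rec2.seq).upper()


def write_fastq(records: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
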