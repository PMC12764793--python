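"""Thin FASTA/FASTQ I/O helpers shared across modules (pysam-backed reading)."""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Iterator, Mapping, NamedTuple

import pysam


class SeqRecord(NamedTuple):
    id: str
    sequence: str
    quality: str | None = None


def read_fastx(path) -> Iterator[SeqRecord]:
    """Iterate records of a FASTA or FASTQ file (gzip handled by htslib)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield SeqRecord(entry.name, entry.sequence, entry.quality)


def read_fasta_dict(path) -> dict[str, str]:
    return {rec.id: rec.sequence for rec in read_fastx(path)}


def write_fasta(path, records: Mapping[str, str] | Iterable[SeqRecord], width: int = 80) -> None:
    if isinstance(records, Mapping):
        records = (SeqRecord(name, seq) for name, seq in records.items())
    with atomic_open(path) as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, records: Iterable[SeqRecord]) -> None:
    with atomic_open(path) as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


class atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path, mode: str = "w"):
        self.path = str(path)
        self.mode = mode
        self._tmp = None

    def __enter__(self):
        d = os.path.dirname(self.path) or "."
        os.makedirs(d, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(self.path))
        self._tmp = tmp
        self._fh = os.fdopen(fd, self.mode)
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
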