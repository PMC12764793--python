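"""Three-way binning of long reads or unitigs with haplotype-specific k-mers.

Each sequence is scored against the two haplotype-specific k-mer sets:
``hits_i`` counts every window occurrence whose canonical k-mer is a member
of set *i*, and the normalized score ``hits_i / |set_i|`` corrects for
unequal set sizes (unequal haplotype divergence). The higher score wins;
exact ties — including zero hits on both sides — leave the sequence
unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from ._seqio import SeqRecord, atomic_open, read_fastx, write_fasta, write_fastq
from .kmerlib import KmerSet, sequence_canonical_codes

__all__ = [
    "BinResult",
    "classify_sequence",
    "partition_sequences",
    "filter_by_length",
    "partition_report",
]

HAP1 = "hap1"
HAP2 = "hap2"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BinResult:
    seq_id: str
    length: int
    hits1: int
    hits2: int
    score1: float
    score2: float
    label: str


def classify_sequence(
    seq_id: str,
    sequence: str,
    set1: KmerSet,
    set2: KmerSet,
    min_hits: int = 0,
) -> BinResult:
    """Classify one sequence as hap1 / hap2 / unassigned.

    ``min_hits`` additionally requires the winning side to reach an absolute
    hit count (0 disables the floor). Empty or sub-k sequences have zero
    hits and are unassigned.
    """
    if set1.k != set2.k:
        raise ValueError(f"k mismatch between specific sets: {set1.k} != {set2.k}")
    codes = sequence_canonical_codes(sequence, set1.k)
    if codes.size:
        hits1 = int(set1.membership(codes).sum())
        hits2 = int(set2.membership(codes).sum())
    else:
        hits1 = hits2 = 0
    score1 = hits1 / len(set1) if len(set1) else 0.0
    score2 = hits2 / len(set2) if len(set2) else 0.0
    if score1 > score2 and hits1 >= min_hits:
        label = HAP1
    elif score2 > score1 and hits2 >= min_hits:
        label = HAP2
    else:
        label = UNASSIGNED
    return BinResult(seq_id, len(sequence), hits1, hits2, score1, score2, label)


def partition_sequences(
    records: Iterable[SeqRecord],
    set1: KmerSet,
    set2: KmerSet,
    min_hits: int = 0,
    unassigned_to_both: bool = False,
) -> tuple[dict[str, list[SeqRecord]], list[BinResult]]:
    """Partition records into hap1/hap2/unassigned bins.

    Returns ({label: records}, table). With ``unassigned_to_both`` the
    unassigned records are additionally appended to both haplotype bins
    (so downstream assembly of either haplotype sees them), while still
    listed once, as unassigned, in the table.
    """
    bins: dict[str, list[SeqRecord]] = {HAP1: [], HAP2: [], UNASSIGNED: []}
    table: list[BinResult] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id}")
        seen.add(rec.id)
        result = classify_sequence(rec.id, rec.sequence, set1, set2, min_hits=min_hits)
        table.append(result)
        bins[result.label].append(rec)
        if unassigned_to_both and result.label == UNASSIGNED:
            bins[HAP1].append(rec)
            bins[HAP2].append(rec)
    return bins, table


def write_partition(
    bins: dict[str, list[SeqRecord]],
    table: list[BinResult],
    outdir,
    fastq: bool = True,
) -> dict[str, str]:
    """Write the three sequence files, the per-read TSV and a summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "fastq" if fastq else "fasta"
    writer = write_fastq if fastq else write_fasta
    paths = {}
    for label in (HAP1, HAP2, UNASSIGNED):
        path = outdir / f"{label}.{ext}"
        writer(path, bins[label])
        paths[label] = str(path)
    tsv = outdir / "binning.tsv"
    with atomic_open(tsv) as fh:
        fh.write("seq_id\tlength\thits1\thits2\tscore1\tscore2\tlabel\n")
        for r in table:
            fh.write(
                f"{r.seq_id}\t{r.length}\t{r.hits1}\t{r.hits2}"
                f"\t{r.score1:.6g}\t{r.score2:.6g}\t{r.label}\n"
            )
    paths["table"] = str(tsv)
    summary = outdir / "summary.json"
    with atomic_open(summary) as fh:
        json.dump(partition_report(table), fh, indent=2)
        fh.write("\n")
    paths["summary"] = str(summary)
    return paths


def filter_by_length(records: Iterable[SeqRecord], min_length: int = 50_000) -> Iterator[SeqRecord]:
    """Yield records with length >= min_length (inclusive), order preserved.

    The 50 kb default is the conventional ultra-long read cutoff.
    """
    for rec in records:
        if len(rec.sequence) >= min_length:
            yield rec


def filter_fastx_by_length(path, out_path, min_length: int = 50_000) -> int:
    """File-level ultra-long filter; returns the number of records kept."""
    kept = list(filter_by_length(read_fastx(path), min_length))
    if kept and kept[0].quality is not None:
        write_fastq(out_path, kept)
    else:
        write_fasta(out_path, kept)
    return len(kept)


def partition_report(table: list[BinResult]) -> dict:
    """Per-label counts, base totals and percentage of total bases."""
    if not table:
        raise ValueError("empty binning table")
    counts = {HAP1: 0, HAP2: 0, UNASSIGNED: 0}
    bases = {HAP1: 0, HAP2: 0, UNASSIGNED: 0}
    for r in table:
        counts[r.label] += 1
        bases[r.label] += r.length
    total_bases = sum(bases.values())
    total_reads = sum(counts.values())
    pct = {
        label: (100.0 * bases[label] / total_bases if total_bases else 0.0)
        for label in bases
    }
    return {
        "n_sequences": total_reads,
        "total_bases": total_bases,
        "counts": counts,
        "bases": bases,
        "percent_bases": pct,
    }
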