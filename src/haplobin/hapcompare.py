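"""Between-haplome sequence comparison.

Two stages: (1) cross-haplome k-mer coverage marks the repetitive fraction
of a haplome — any position covered at least twice by 27-mers from the
other haplome — so that nonrepetitive sequence can be extracted and
aligned; (2) extended-CIGAR alignments of those sequences are decomposed
into matched bases, SNVs, small indels (< 50 bp), PAVs (>= 50 bp,
including terminal soft-clips of that size) and soft-clipped bases, with
per-alignment identity = matched bases / total alignment length (matches,
mismatches, insertions, deletions and soft-clipped bases).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kmerlib import KmerSet, count_canonical, encode_bases, _window_codes

__all__ = [
    "AlignmentRecord",
    "VariationBreakdown",
    "kmer_position_coverage",
    "mask_repetitive",
    "extract_intervals",
    "filter_alignments",
    "parse_cigar_variation",
    "identity_summary",
    "windowed_category_coverage",
    "read_paf_alignments",
    "FILTER_PRESETS",
]

SV_CUTOFF = 50

# (min query span, min mapq); all thresholds inclusive — "dotplot" MQ > 0
# is encoded as MQ >= 1 since mapping qualities are integers.
FILTER_PRESETS = {
    "synteny": (2_000, 60),
    "dotplot": (2_000, 1),
    "unitig": (100, 50),
}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignmentRecord:
    query: str
    query_len: int
    query_start: int
    query_end: int
    target: str
    target_start: int
    target_end: int
    strand: str = "+"
    mapq: int = 60
    primary: bool = True
    cigar: str = ""

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class VariationBreakdown:
    """Decomposition of one alignment into variation categories.

    ``pav_internal_len`` counts only PAV bases arising from I/D operations;
    soft-clip bases are tallied once, in ``sc_len``, even when a clip of
    >= 50 bp also counts toward ``pav_count``/``pav_len``. The base
    conservation identity is
    match + snv + indel + pav_internal + sc = total.
    """

    match_len: int
    snv_count: int
    snv_len: int
    indel_count: int
    indel_len: int
    pav_count: int
    pav_len: int
    pav_internal_len: int
    sc_len: int
    total_len: int

    @property
    def identity(self) -> float:
        return self.match_len / self.total_len if self.total_len else 0.0


def parse_cigar_variation(record: AlignmentRecord | str, sv_cutoff: int = SV_CUTOFF) -> VariationBreakdown:
    """Parse an extended CIGAR (=/X) into the variation breakdown.

    Insertion/deletion runs shorter than ``sv_cutoff`` are small indels;
    runs at or above it are PAVs. Soft-clips go to ``sc_len`` and, when
    >= ``sv_cutoff``, also count as PAV events. Hard-clips are ignored.
    An ambiguous "M" operation raises: realign with extended CIGAR output
    (minimap2 --eqx).
    """
    cigar = record.cigar if isinstance(record, AlignmentRecord) else record
    match_len = snv_count = snv_len = 0
    indel_count = indel_len = 0
    pav_count = pav_len = pav_internal = 0
    sc_len = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op == "M":
            raise ValueError(
                "ambiguous 'M' CIGAR operation: re-run the aligner with "
                "extended CIGAR output (e.g. minimap2 --eqx)"
            )
        if op == "=":
            match_len += n
        elif op == "X":
            snv_count += n
            snv_len += n
        elif op in "ID":
            if n < sv_cutoff:
                indel_count += 1
                indel_len += n
            else:
                pav_count += 1
                pav_len += n
                pav_internal += n
        elif op == "S":
            sc_len += n
            if n >= sv_cutoff:
                pav_count += 1
                pav_len += n
        elif op in "HNP":
            continue
        consumed += n
    total = match_len + snv_len + indel_len + pav_internal + sc_len
    return VariationBreakdown(
        match_len, snv_count, snv_len, indel_count, indel_len,
        pav_count, pav_len, pav_internal, sc_len, total,
    )


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_len: int | None = None,
    min_mapq: int | None = None,
    primary_only: bool = True,
    preset: str | None = None,
) -> list[AlignmentRecord]:
    """Filter alignments by query span and mapping quality (inclusive).

    ``preset`` selects the named threshold pair from :data:`FILTER_PRESETS`;
    explicit ``min_len``/``min_mapq`` override preset values. Alignment
    length is the query span (query_end - query_start) uniformly.
    """
    if preset is not None:
        p_len, p_mq = FILTER_PRESETS[preset]
        min_len = p_len if min_len is None else min_len
        min_mapq = p_mq if min_mapq is None else min_mapq
    min_len = 0 if min_len is None else min_len
    min_mapq = 0 if min_mapq is None else min_mapq
    return [
        r for r in records
        if (not primary_only or r.primary)
        and r.query_span >= min_len
        and r.mapq >= min_mapq
    ]


def kmer_position_coverage(
    target_sequences: dict[str, str],
    source_sequences: dict[str, str],
    k: int = 27,
) -> dict[str, np.ndarray]:
    """Per-base occurrence count of each target position's k-mer in the source.

    The coverage at position p is the source-multiset count of the
    canonical k-mer starting at p. Positions without a valid start
    (including the trailing k-1 bases) inherit the count of the last valid
    k-mer start; positions whose own base is not A/C/G/T get 0. With
    ``source == target`` this is the self-repeat mode (coverage >= 2 marks
    a repeat).
    """
    source_set = count_canonical(list(source_sequences.values()), k) \
        if source_sequences else KmerSet.empty(k)

    out: dict[str, np.ndarray] = {}
    for chrom, seq in target_sequences.items():
        L = len(seq)
        cov = np.zeros(L, dtype=np.int64)
        base_codes = encode_bases(seq)
        codes, valid = _window_codes(base_codes, k)
        if codes.size:
            if len(source_set):
                idx = np.searchsorted(source_set.codes, codes)
                idx = np.minimum(idx, len(source_set) - 1)
                member = source_set.codes[idx] == codes
                counts = np.where(member, source_set.counts[idx], 0)
            else:
                counts = np.zeros(codes.shape, dtype=np.int64)
            starts = np.flatnonzero(valid)
            vals = np.zeros(valid.shape[0], dtype=np.int64)
            vals[starts] = counts
            # forward-fill from the last valid start across invalid starts
            # and the trailing k-1 positions
            last_valid = np.full(L, -1, dtype=np.int64)
            last_valid[starts] = starts
            last_valid = np.maximum.accumulate(last_valid)
            has = last_valid >= 0
            cov[has] = vals[last_valid[has]]
        cov[base_codes > 3] = 0
        out[chrom] = cov
    return out


Bed = list[tuple[str, int, int]]


def mask_repetitive(
    sequences: dict[str, str],
    coverage: dict[str, np.ndarray],
    min_cov: int = 2,
) -> tuple[dict[str, str], Bed, Bed]:
    """Mask positions with coverage >= min_cov to N.

    Returns (masked sequences, repeat BED, nonrepetitive BED); the
    nonrepetitive BED lists maximal runs of unmasked non-N positions.
    Intervals are 0-based half-open. Masking is idempotent for a fixed
    coverage track.
    """
    masked: dict[str, str] = {}
    repeat_bed: Bed = []
    nonrep_bed: Bed = []
    for chrom, seq in sequences.items():
        cov = coverage[chrom]
        if cov.shape[0] != len(seq):
            raise ValueError(f"coverage track length mismatch on {chrom}")
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
        rep = cov >= min_cov
        arr[rep] = ord("N")
        masked[chrom] = arr.tobytes().decode("ascii")
        repeat_bed.extend((chrom, s, e) for s, e in _runs(rep))
        nonrep = (~rep) & (arr != ord("N"))
        nonrep_bed.extend((chrom, s, e) for s, e in _runs(nonrep))
    return masked, repeat_bed, nonrep_bed


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.shape[0] == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def extract_intervals(sequences: dict[str, str], bed: Bed) -> dict[str, str]:
    """Extract BED intervals as sequences with "chrom:start-end" identifiers."""
    out = {}
    for chrom, start, end in bed:
        out[f"{chrom}:{start}-{end}"] = sequences[chrom][start:end]
    return out


def windowed_category_coverage(
    repeat_bed: Bed,
    nonrep_bed: Bed,
    chrom_lengths: dict[str, int],
    window_size: int = 1_000_000,
) -> pd.DataFrame:
    """Count repetitive, nonrepetitive and N bases per genomic window.

    The two BEDs must be disjoint; per window, repetitive + nonrepetitive
    + N equals the window length (N is the remainder: gaps and masked
    bases belonging to neither BED).
    """
    _check_disjoint(repeat_bed, nonrep_bed)
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n_windows = max(1, -(-L // window_size))
        rep = np.zeros(n_windows, dtype=np.int64)
        nonrep = np.zeros(n_windows, dtype=np.int64)
        for bed, acc in ((repeat_bed, rep), (nonrep_bed, nonrep)):
            for c, s, e in bed:
                if c != chrom:
                    continue
                for w in range(s // window_size, (max(e - 1, s)) // window_size + 1):
                    ws, we = w * window_size, min((w + 1) * window_size, L)
                    acc[w] += max(0, min(e, we) - max(s, ws))
        for w in range(n_windows):
            ws, we = w * window_size, min((w + 1) * window_size, L)
            rows.append({
                "chrom": chrom,
                "start": ws,
                "end": we,
                "repetitive": int(rep[w]),
                "nonrepetitive": int(nonrep[w]),
                "n_bases": int(we - ws - rep[w] - nonrep[w]),
            })
    return pd.DataFrame(rows)


def _check_disjoint(bed_a: Bed, bed_b: Bed) -> None:
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for label, bed in enumerate((bed_a, bed_b)):
        for chrom, s, e in bed:
            by_chrom.setdefault(chrom, []).append((s, e, label))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1, _), (s2, _e2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping BED intervals on {chrom} near {s2}")


def identity_summary(
    breakdowns: Sequence[VariationBreakdown],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median/quartile identity and category proportions per group.

    ``groups`` assigns each breakdown to a group (e.g. target chromosome);
    omitted, all alignments form one group. Category proportions are
    aggregate base fractions of the summed alignment length.
    """
    if not breakdowns:
        raise ValueError("no alignments to summarise")
    if groups is None:
        groups = ["all"] * len(breakdowns)
    df = pd.DataFrame({
        "group": list(groups),
        "identity": [b.identity for b in breakdowns],
        "match": [b.match_len for b in breakdowns],
        "snv": [b.snv_len for b in breakdowns],
        "indel": [b.indel_len for b in breakdowns],
        "pav_internal": [b.pav_internal_len for b in breakdowns],
        "sc": [b.sc_len for b in breakdowns],
        "total": [b.total_len for b in breakdowns],
    })
    def _agg(g: pd.DataFrame) -> pd.Series:
        total = g["total"].sum()
        return pd.Series({
            "n_alignments": len(g),
            "median_identity": g["identity"].median(),
            "q1_identity": g["identity"].quantile(0.25),
            "q3_identity": g["identity"].quantile(0.75),
            "match_frac": g["match"].sum() / total,
            "snv_frac": g["snv"].sum() / total,
            "indel_frac": g["indel"].sum() / total,
            "pav_frac": g["pav_internal"].sum() / total,
            "sc_frac": g["sc"].sum() / total,
        })
    return df.groupby("group").apply(_agg, include_groups=False)


def read_paf_alignments(path) -> list[AlignmentRecord]:
    """Read PAF records carrying cg:Z extended CIGARs (tp:A marks primary)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed PAF at {path}:{i}: fewer than 12 columns")
            cigar = ""
            primary = True
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
                elif tag.startswith("tp:A:"):
                    primary = tag[5:] == "P"
            out.append(AlignmentRecord(
                query=f[0], query_len=int(f[1]),
                query_start=int(f[2]), query_end=int(f[3]),
                strand=f[4], target=f[5],
                target_start=int(f[7]), target_end=int(f[8]),
                mapq=int(f[11]), primary=primary, cigar=cigar,
            ))
    return out
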