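"""Canonical k-mer counting and set algebra.

Haplotype-specific k-mers — k-mers present in one haplotype sequence and
absent from the other — are the signal used to bin long reads and unitigs.
This module provides the counting and subtraction primitives behind that:
canonical k-mer extraction (lexicographic minimum of a k-mer and its
reverse complement), multiset counting, and presence/absence subtraction.

K-mers are held as 2-bit-packed unsigned 64-bit integers internally
(A=0, C=1, G=2, T=3, most significant bits first), which caps k at 32;
the public contract is defined on strings. Windows containing any non-ACGT
symbol are skipped entirely.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "KmerSet",
    "count_canonical",
    "subtract",
    "haplotype_specific_kmers",
    "canonical",
    "reverse_complement",
]

MAX_K = 32

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte value -> 2-bit code; 4 marks an invalid (non-ACGT) base
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Return the lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to per-base 2-bit codes (4 for non-ACGT)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed forward and reverse-complement codes for every length-k window.

    Returns (canonical codes of valid windows, boolean validity per start).
    """
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (codes > 3).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0

    safe = np.where(codes > 3, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + n]
        rev |= (np.uint64(3) - safe[j : j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[valid], valid


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(int(code) >> shift) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    codes = encode_bases(kmer)
    if (codes > 3).any():
        raise ValueError(f"k-mer contains non-ACGT symbols: {kmer!r}")
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


class KmerSet:
    """A collection of canonical k-mers with occurrence counts.

    Backed by a sorted uint64 code array and a parallel count array, which
    keeps membership queries (`searchsorted`) and set subtraction vectorised.
    """

    __slots__ = ("k", "codes", "counts")

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
        self.k = int(k)
        self.codes = np.asarray(codes, dtype=np.uint64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must have equal length")

    @classmethod
    def empty(cls, k: int) -> "KmerSet":
        return cls(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))

    @classmethod
    def from_dict(cls, k: int, counts: Mapping[str, int]) -> "KmerSet":
        """Build from a {k-mer string: count} mapping; keys are canonicalised."""
        agg: dict[int, int] = {}
        for kmer, c in counts.items():
            if len(kmer) != k:
                raise ValueError(f"k-mer {kmer!r} does not have length {k}")
            code = encode_kmer(canonical(kmer.upper()))
            agg[code] = agg.get(code, 0) + int(c)
        codes = np.array(sorted(agg), dtype=np.uint64)
        cnts = np.array([agg[int(c)] for c in codes], dtype=np.int64)
        return cls(k, codes, cnts)

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        try:
            code = encode_kmer(canonical(kmer.upper()))
        except ValueError:
            return False
        i = np.searchsorted(self.codes, np.uint64(code))
        return bool(i < len(self.codes) and self.codes[i] == np.uint64(code))

    def get(self, kmer: str, default: int = 0) -> int:
        if kmer not in self:
            return default
        code = np.uint64(encode_kmer(canonical(kmer.upper())))
        i = np.searchsorted(self.codes, code)
        return int(self.counts[i])

    def to_dict(self) -> dict[str, int]:
        return {
            decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def items(self) -> Iterator[tuple[str, int]]:
        for c, n in zip(self.codes, self.counts):
            yield decode_kmer(int(c), self.k), int(n)

    def total(self) -> int:
        """Total k-mer occurrences (sum of counts)."""
        return int(self.counts.sum())

    def membership(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership test for an array of canonical codes."""
        if len(self) == 0:
            return np.zeros(codes.shape, dtype=bool)
        idx = np.searchsorted(self.codes, codes)
        idx = np.minimum(idx, len(self) - 1)
        return self.codes[idx] == codes

    def filter_min_count(self, min_count: int) -> "KmerSet":
        keep = self.counts >= min_count
        return KmerSet(self.k, self.codes[keep], self.counts[keep])

    # ------------------------------------------------------------------
    # text serialisation: sorted two-column (k-mer, count), tab separated
    # ------------------------------------------------------------------
    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer, count in self.items():
                fh.write(f"{kmer}\t{count}\n")

    @classmethod
    def read(cls, path) -> "KmerSet":
        k = None
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#k="):
                        k = int(line[3:])
                    continue
                kmer, count = line.split("\t")
                counts[kmer] = int(count)
        if k is None:
            if not counts:
                raise ValueError(f"cannot infer k from empty file {path}")
            k = len(next(iter(counts)))
        return cls.from_dict(k, counts)


def count_canonical(sequences: Iterable[str] | str, k: int) -> KmerSet:
    """Count canonical k-mers over one or more sequences.

    Every length-k window consisting solely of A/C/G/T (case-insensitive)
    contributes one occurrence to its canonical k-mer; windows containing
    any other symbol are skipped. Sequences shorter than k contribute
    nothing, so the result may be empty.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    if isinstance(sequences, str):
        sequences = [sequences]
    chunks = []
    for seq in sequences:
        codes, _ = _window_codes(encode_bases(seq), k)
        if codes.size:
            chunks.append(codes)
    if not chunks:
        return KmerSet.empty(k)
    all_codes = np.concatenate(chunks)
    uniq, counts = np.unique(all_codes, return_counts=True)
    return KmerSet(k, uniq, counts.astype(np.int64))


def sequence_canonical_codes(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every valid window of one sequence, in order."""
    codes, _ = _window_codes(encode_bases(seq), k)
    return codes


def subtract(a: KmerSet, b: KmerSet) -> KmerSet:
    """K-mers present in `a` and absent from `b`, keeping `a`'s counts.

    Presence/absence semantics: `b`'s counts are ignored — haplotype
    specificity is a membership question, not an abundance one.
    """
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} != {b.k}")
    keep = ~b.membership(a.codes)
    return KmerSet(a.k, a.codes[keep], a.counts[keep])


def haplotype_specific_kmers(
    hap1_sequences: Iterable[str] | str,
    hap2_sequences: Iterable[str] | str,
    k: int = 21,
    min_count: int = 1,
) -> tuple[KmerSet, KmerSet]:
    """Extract the k-mers unique to each haplotype.

    set1 = kmers(hap1) − kmers(hap2) and vice versa; the two results are
    disjoint by construction. `min_count` optionally drops specific k-mers
    seen fewer times (default 1 applies no floor).
    """
    set1 = count_canonical(hap1_sequences, k)
    set2 = count_canonical(hap2_sequences, k)
    spec1 = subtract(set1, set2)
    spec2 = subtract(set2, set1)
    if min_count > 1:
        spec1 = spec1.filter_min_count(min_count)
        spec2 = spec2.filter_min_count(min_count)
    return spec1, spec2
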