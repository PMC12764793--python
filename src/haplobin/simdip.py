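"""Synthetic diploid genomes, mosaic references, phased VCFs and long reads.

Every downstream stage of the toolkit — haplotype consensus, specific-k-mer
extraction, read binning, purging and phasing evaluation — is exercised
against data from this module, which carries full ground truth: the exact
variant list distinguishing the two haplotypes, the source haplotype of
every simulated read, the mosaic block structure of the haploid reference,
and the positions where phase was deliberately flipped in the emitted VCF.

Haplotype 1 serves as the coordinate baseline: haplotype 2 is derived from
it by applying sampled heterozygous variants (SNVs, small indels < 50 bp,
and PAVs >= 50 bp — presence/absence segments, modelled as an insertion
relative to the haplotype lacking them). Variants are placed without
overlap by rejection sampling so the truth is never ambiguous. All internal
coordinates are 0-based half-open; emitted VCFs are 1-based per the
standard.

Default heterozygosity follows a highly heterozygous outcrossing grass
genome: one heterozygous SNV per 20 bp (snv_rate 0.05) across seven
chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seqio import SeqRecord, atomic_open
from .hapconsensus import PhasedVariant

__all__ = [
    "DiploidSimConfig",
    "Variant",
    "MosaicBlock",
    "TruthSet",
    "simulate_diploid",
    "make_mosaic_reference",
    "emit_phased_vcf",
    "simulate_reads",
    "write_vcf",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SNV = "SNV"
INDEL = "INDEL"
PAV = "PAV"

SV_CUTOFF = 50  # events >= 50 bp are PAVs, < 50 bp small indels


@dataclass(frozen=True)
class DiploidSimConfig:
    """Parameters of the simulated diploid.

    Rates are per base of haplotype 1; the default SNV rate of 0.05
    corresponds to one heterozygous SNV per 20 bp. ``indel_max_len`` must
    stay below 50 bp and ``pav_len_range`` at or above 50 bp so the
    simulated variant classes respect the structural-variant cutoff.
    """

    n_chromosomes: int = 7
    chrom_length: int = 1_000_000
    snv_rate: float = 0.05
    indel_rate: float = 0.0
    indel_max_len: int = 10
    pav_rate: float = 0.0
    pav_len_range: tuple[int, int] = (50, 500)
    repeat_fraction: float = 0.0
    repeat_unit_length: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be positive")
        if self.chrom_length < 1:
            raise ValueError("chrom_length must be positive")
        for name in ("snv_rate", "indel_rate", "pav_rate", "repeat_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.indel_max_len < SV_CUTOFF:
            raise ValueError(f"indel_max_len must be in [1, {SV_CUTOFF})")
        lo, hi = self.pav_len_range
        if lo < SV_CUTOFF or hi < lo:
            raise ValueError(f"pav_len_range must satisfy {SV_CUTOFF} <= lo <= hi")
        if self.pav_rate > 0 and self.pav_len_range[1] + 2 > self.chrom_length:
            raise ValueError(
                "chromosome too short to host requested PAV lengths: "
                f"chrom_length={self.chrom_length}, max PAV={self.pav_len_range[1]}"
            )
        if self.repeat_fraction >= 1:
            raise ValueError("repeat_fraction must be < 1")


@dataclass(frozen=True)
class Variant:
    """One heterozygous difference between the haplotypes.

    ``pos`` is 0-based on haplotype 1; ``ref`` is the haplotype-1 allele and
    ``alt`` the allele carried by ``hap_alt`` (haplotype 2 under the
    baseline convention). Indels follow the VCF anchored-base convention.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str  # SNV | INDEL | PAV
    hap_alt: int = 2

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.pos, self.pos + len(self.ref)


@dataclass(frozen=True)
class MosaicBlock:
    """One block of the mosaic haploid reference.

    ``start``/``end`` are reference coordinates; ``hap1_start``/``hap1_end``
    give the corresponding haplotype-1 interval the block was lifted from.
    """

    chrom: str
    start: int
    end: int
    source_hap: int
    hap1_start: int
    hap1_end: int


@dataclass
class TruthSet:
    """Ground truth accompanying one simulated dataset."""

    variants: list[Variant] = field(default_factory=list)
    read_labels: dict[str, int] = field(default_factory=dict)
    switch_points: list[tuple[str, int]] = field(default_factory=list)
    mosaic_blocks: list[MosaicBlock] = field(default_factory=list)
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def variants_for(self, chrom: str) -> list[Variant]:
        return [v for v in self.variants if v.chrom == chrom]

    def validate(self) -> None:
        by_chrom: dict[str, int] = {}
        for v in self.variants:
            if not v.ref or not v.alt:
                raise ValueError(f"empty allele at {v.chrom}:{v.pos}")
            if v.vclass == SNV and (len(v.ref) != 1 or len(v.alt) != 1):
                raise ValueError(f"SNV alleles must have length 1 at {v.chrom}:{v.pos}")
            prev = by_chrom.get(v.chrom, -1)
            if v.pos <= prev:
                raise ValueError(
                    f"variant positions not strictly increasing on {v.chrom}: "
                    f"{v.pos} after {prev}"
                )
            by_chrom[v.chrom] = v.pos

    def write_tsv(self, path) -> None:
        """Write the variant and mosaic-block tables as one TSV."""
        with atomic_open(path) as fh:
            fh.write("#section\tchrom\tpos\tref\talt\tclass\thap_alt\n")
            for v in self.variants:
                fh.write(
                    f"variant\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vclass}\t{v.hap_alt}\n"
                )
            for b in self.mosaic_blocks:
                fh.write(
                    f"mosaic_block\t{b.chrom}\t{b.start}-{b.end}\thap{b.source_hap}"
                    f"\t{b.hap1_start}-{b.hap1_end}\t.\t.\n"
                )
            for chrom, pos in self.switch_points:
                fh.write(f"switch_point\t{chrom}\t{pos}\t.\t.\t.\t.\n")
            for chrom, s, e in self.repeat_intervals:
                fh.write(f"repeat\t{chrom}\t{s}-{e}\t.\t.\t.\t.\n")
            for rid, hap in self.read_labels.items():
                fh.write(f"read_label\t{rid}\t{hap}\t.\t.\t.\t.\n")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _sample_positions(
    rng: np.random.Generator,
    occupied: np.ndarray,
    n_events: int,
    span: int,
    limit: int,
) -> list[int]:
    """Rejection-sample non-overlapping start positions for fixed-span events."""
    out: list[int] = []
    attempts = 0
    max_attempts = 200 * max(n_events, 1) + 1000
    while len(out) < n_events and attempts < max_attempts:
        attempts += 1
        p = int(rng.integers(1, limit - span))
        if occupied[p : p + span + 1].any():
            continue
        occupied[p : p + span + 1] = True
        out.append(p)
    if len(out) < n_events:
        raise ValueError(
            f"could not place {n_events} events of span {span} without overlap; "
            "lower the rates or lengthen the chromosome"
        )
    return out


def simulate_diploid(config: DiploidSimConfig) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Simulate the two haplotypes of a diploid and the variant truth.

    Returns (hap1 sequences, hap2 sequences, TruthSet); chromosome names are
    ``chr1..chrN``. Identical config and seed give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hap1: dict[str, str] = {}
    hap2: dict[str, str] = {}
    truth = TruthSet()

    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        L = config.chrom_length
        seq = _random_sequence(rng, L)

        # plant a multicopy repeat shared by both haplotypes
        if config.repeat_fraction > 0:
            unit_len = min(config.repeat_unit_length, L // 4)
            n_copies = max(2, int(round(config.repeat_fraction * L / unit_len)))
            unit = _random_sequence(rng, unit_len)
            occ = np.zeros(L, dtype=bool)
            starts = _sample_positions(rng, occ, n_copies, unit_len, L - unit_len)
            for s in sorted(starts):
                seq[s : s + unit_len] = unit
                truth.repeat_intervals.append((chrom, s, s + unit_len))

        occupied = np.zeros(L, dtype=bool)
        events: list[Variant] = []

        # PAVs first (largest spans), then indels, then SNVs
        n_pav = int(rng.binomial(L, config.pav_rate)) if config.pav_rate > 0 else 0
        for _ in range(n_pav):
            length = int(rng.integers(config.pav_len_range[0], config.pav_len_range[1] + 1))
            deletion = bool(rng.random() < 0.5)  # hap2 lacks a hap1 segment
            span = length + 1 if deletion else 1
            if span + 2 >= L:
                raise ValueError("chromosome too short to host requested PAV lengths")
            p = _sample_positions(rng, occupied, 1, span, L - span)[0]
            if deletion:
                ref = _to_str(seq[p : p + length + 1])
                alt = ref[0]
            else:
                ref = _to_str(seq[p : p + 1])
                alt = ref + _to_str(_random_sequence(rng, length))
            events.append(Variant(chrom, p, ref, alt, PAV))

        n_indel = int(rng.binomial(L, config.indel_rate)) if config.indel_rate > 0 else 0
        for _ in range(n_indel):
            length = int(rng.integers(1, config.indel_max_len + 1))
            deletion = bool(rng.random() < 0.5)
            span = length + 1 if deletion else 1
            p = _sample_positions(rng, occupied, 1, span, L - span)[0]
            if deletion:
                ref = _to_str(seq[p : p + length + 1])
                alt = ref[0]
            else:
                ref = _to_str(seq[p : p + 1])
                alt = ref + _to_str(_random_sequence(rng, length))
            events.append(Variant(chrom, p, ref, alt, INDEL))

        n_snv = int(rng.binomial(L, config.snv_rate)) if config.snv_rate > 0 else 0
        if n_snv:
            positions = _sample_positions(rng, occupied, n_snv, 1, L - 1)
            offsets = rng.integers(1, 4, size=n_snv)
            for p, off in zip(positions, offsets):
                ref = chr(seq[p])
                alt = "ACGT"[("ACGT".index(ref) + int(off)) % 4]
                events.append(Variant(chrom, p, ref, alt, SNV))

        events.sort(key=lambda v: v.pos)
        truth.variants.extend(events)

        hap1[chrom] = _to_str(seq)
        hap2[chrom] = _apply_variants(hap1[chrom], events)

    truth.validate()
    return hap1, hap2, truth


def _apply_variants(sequence: str, variants: list[Variant]) -> str:
    """Apply sorted, non-overlapping variants (alt alleles) to a sequence."""
    parts: list[str] = []
    cursor = 0
    for v in variants:
        if sequence[v.pos : v.pos + len(v.ref)] != v.ref:
            raise AssertionError(f"ref mismatch at {v.chrom}:{v.pos}")
        parts.append(sequence[cursor : v.pos])
        parts.append(v.alt)
        cursor = v.pos + len(v.ref)
    parts.append(sequence[cursor:])
    return "".join(parts)


def _hap2_offsets(variants: list[Variant]) -> list[int]:
    """Cumulative hap1->hap2 coordinate offset *before* each variant."""
    offsets = []
    acc = 0
    for v in variants:
        offsets.append(acc)
        acc += len(v.alt) - len(v.ref)
    return offsets


def make_mosaic_reference(
    hap1: dict[str, str],
    hap2: dict[str, str],
    truth: TruthSet,
    n_switches_per_chrom: int,
    seed: int = 0,
) -> tuple[dict[str, str], TruthSet]:
    """Build a haploid reference alternating between the two haplotypes.

    Haplotype blocks alternate starting from haplotype 1; switch boundaries
    are drawn uniformly but never inside a variant's reference span, so a
    PAV allele is never split between blocks. ``n_switches_per_chrom = 0``
    returns haplotype 1 verbatim.
    """
    if n_switches_per_chrom < 0:
        raise ValueError("n_switches_per_chrom must be >= 0")
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    blocks: list[MosaicBlock] = []

    for chrom, seq1 in hap1.items():
        variants = truth.variants_for(chrom)
        offsets = _hap2_offsets(variants)
        L = len(seq1)

        forbidden = np.zeros(L, dtype=bool)
        for v in variants:
            s, e = v.ref_span
            forbidden[s : min(e + 1, L)] = True

        cuts: set[int] = set()
        attempts = 0
        while len(cuts) < n_switches_per_chrom and attempts < 10000:
            attempts += 1
            p = int(rng.integers(1, L))
            if not forbidden[p]:
                cuts.add(p)
        if len(cuts) < n_switches_per_chrom:
            raise ValueError(f"could not place {n_switches_per_chrom} switches on {chrom}")

        bounds = [0, *sorted(cuts), L]
        parts: list[str] = []
        ref_cursor = 0
        for i in range(len(bounds) - 1):
            h1s, h1e = bounds[i], bounds[i + 1]
            source = 1 if i % 2 == 0 else 2
            if source == 1:
                piece = seq1[h1s:h1e]
            else:
                h2s = h1s + _offset_at(variants, offsets, h1s)
                h2e = h1e + _offset_at(variants, offsets, h1e)
                piece = hap2[chrom][h2s:h2e]
            blocks.append(
                MosaicBlock(chrom, ref_cursor, ref_cursor + len(piece), source, h1s, h1e)
            )
            parts.append(piece)
            ref_cursor += len(piece)
        reference[chrom] = "".join(parts)

    updated = replace_truth(truth, mosaic_blocks=blocks)
    return reference, updated


def _offset_at(variants: list[Variant], offsets: list[int], hap1_pos: int) -> int:
    """hap1->hap2 offset in effect at a position outside all ref spans."""
    acc = 0
    for v, off in zip(variants, offsets):
        if v.pos + len(v.ref) <= hap1_pos:
            acc = off + len(v.alt) - len(v.ref)
        else:
            break
    return acc


def replace_truth(truth: TruthSet, **kwargs) -> TruthSet:
    data = dict(
        variants=truth.variants,
        read_labels=truth.read_labels,
        switch_points=truth.switch_points,
        mosaic_blocks=truth.mosaic_blocks,
        repeat_intervals=truth.repeat_intervals,
    )
    data.update(kwargs)
    return TruthSet(**data)


def emit_phased_vcf(
    truth: TruthSet,
    reference: dict[str, str],
    switch_error_rate: float = 0.0,
    seed: int = 0,
    mapq: int = 60,
    depth: int = 30,
) -> tuple[list[PhasedVariant], TruthSet]:
    """Produce phased heterozygous records in reference coordinates.

    The reference is either haplotype 1 or a mosaic built by
    :func:`make_mosaic_reference` (detected via ``truth.mosaic_blocks``).
    Genotypes are pipe-separated with one phase set per chromosome. Each
    site's phase is flipped independently with probability
    ``switch_error_rate``; flip positions (0-based reference coordinates)
    are appended to ``switch_points`` in the returned TruthSet.

    Every emitted record's REF allele is checked against the reference
    sequence; a mismatch indicates an inconsistent TruthSet and raises.
    """
    if not 0 <= switch_error_rate <= 1:
        raise ValueError("switch_error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[PhasedVariant] = []
    switch_points = list(truth.switch_points)

    blocks_by_chrom: dict[str, list[MosaicBlock]] = {}
    for b in truth.mosaic_blocks:
        blocks_by_chrom.setdefault(b.chrom, []).append(b)

    for chrom in reference:
        variants = truth.variants_for(chrom)
        if not variants:
            continue
        offsets = _hap2_offsets(variants)
        blocks = blocks_by_chrom.get(chrom)
        phase_set = str(variants[0].pos + 1)  # first site, 1-based: one PS per chrom

        for v, h2off in zip(variants, offsets):
            if blocks is None:
                ref_pos, ref_allele, alt_allele, phase = v.pos, v.ref, v.alt, (0, 1)
            else:
                blk = _containing_block(blocks, v.pos)
                if blk.source_hap == 1:
                    ref_pos = v.pos - blk.hap1_start + blk.start
                    ref_allele, alt_allele, phase = v.ref, v.alt, (0, 1)
                else:
                    hap2_pos = v.pos + h2off
                    hap2_block_start = blk.hap1_start + _offset_at(variants, offsets, blk.hap1_start)
                    ref_pos = hap2_pos - hap2_block_start + blk.start
                    ref_allele, alt_allele, phase = v.alt, v.ref, (1, 0)

            observed = reference[chrom][ref_pos : ref_pos + len(ref_allele)]
            if observed != ref_allele:
                raise AssertionError(
                    f"TruthSet inconsistent with reference at {chrom}:{ref_pos}: "
                    f"expected {ref_allele!r}, found {observed!r}"
                )

            if rng.random() < switch_error_rate:
                phase = (phase[1], phase[0])
                switch_points.append((chrom, ref_pos))

            records.append(
                PhasedVariant(
                    chrom=chrom,
                    pos=ref_pos + 1,
                    ref=ref_allele,
                    alt=alt_allele,
                    phase=phase,
                    phase_set=phase_set,
                    mapq=mapq,
                    depth=depth,
                )
            )

    return records, replace_truth(truth, switch_points=switch_points)


def _containing_block(blocks: list[MosaicBlock], hap1_pos: int) -> MosaicBlock:
    for b in blocks:
        if b.hap1_start <= hap1_pos < b.hap1_end:
            return b
    raise ValueError(f"no mosaic block contains haplotype-1 position {hap1_pos}")


def write_vcf(records: list[PhasedVariant], reference: dict[str, str], path) -> None:
    """Write phased records as an uncompressed VCF with GT|PS formatting."""
    with atomic_open(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplobin-simdip\n")
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in records:
            gt = f"{r.phase[0]}|{r.phase[1]}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t60\tPASS\t"
                f"MQ={r.mapq};DP={r.depth}\tGT:PS\t{gt}:{r.phase_set}\n"
            )


def simulate_reads(
    haplotypes: tuple[dict[str, str], dict[str, str]],
    read_length_mean: int = 20_000,
    read_length_min: int = 1_000,
    read_length_max: int | None = None,
    n_reads: int | None = None,
    depth: float | None = None,
    error_rate: float = 0.0,
    length_sigma: float = 1.3,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Sample error-bearing long reads evenly from both haplotypes.

    Read lengths follow a log-normal with the requested mean (``length_sigma``
    is the log-scale spread), clipped to [min, max] and to the chromosome
    length. Reads are drawn from both haplotypes and both strands with equal
    probability. Errors are applied per base at ``error_rate`` with a
    60:20:20 substitution:insertion:deletion split. Exactly one of
    ``n_reads`` or ``depth`` must be given; ``depth`` targets total read
    bases of ``depth`` times the diploid genome size.
    """
    if (n_reads is None) == (depth is None):
        raise ValueError("specify exactly one of n_reads or depth")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    hap1, hap2 = haplotypes
    haps = {1: hap1, 2: hap2}
    min_chrom = min(len(s) for h in haps.values() for s in h.values())
    if read_length_min > min_chrom:
        raise ValueError(
            f"requested minimum read length {read_length_min} exceeds the "
            f"shortest chromosome ({min_chrom} bp)"
        )
    if read_length_max is None:
        read_length_max = 4 * read_length_mean

    rng = np.random.default_rng(seed)
    genome_size = sum(len(s) for h in haps.values() for s in h.values())
    target_bases = None if depth is None else int(depth * genome_size)

    # per-haplotype chromosome sampling weights proportional to length
    chrom_tables = {}
    for h, seqs in haps.items():
        names = list(seqs)
        lengths = np.array([len(seqs[n]) for n in names], dtype=float)
        chrom_tables[h] = (names, lengths / lengths.sum())

    mu = math.log(read_length_mean) - length_sigma**2 / 2

    records: list[SeqRecord] = []
    labels: dict[str, int] = {}
    total_bases = 0
    i = 0
    while True:
        if n_reads is not None and i >= n_reads:
            break
        if target_bases is not None and total_bases >= target_bases:
            break
        hap = 1 if rng.random() < 0.5 else 2
        names, weights = chrom_tables[hap]
        chrom = names[int(rng.choice(len(names), p=weights))]
        seq = haps[hap][chrom]
        length = int(np.clip(rng.lognormal(mu, length_sigma), read_length_min, read_length_max))
        length = min(length, len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        read = np.frombuffer(seq[start : start + length].encode("ascii"), dtype=np.uint8).copy()
        reverse = bool(rng.random() < 0.5)
        if reverse:
            read = _revcomp_codes(read)
        if error_rate > 0:
            read = _apply_read_errors(rng, read, error_rate)
        rid = f"read{i:07d}"
        records.append(SeqRecord(rid, read.tobytes().decode("ascii"), "I" * read.shape[0]))
        labels[rid] = hap
        total_bases += read.shape[0]
        i += 1
    return records, labels


_RC_TABLE = np.zeros(256, dtype=np.uint8)
for _f, _r in zip(b"ACGTacgtN", b"TGCAtgcaN"):
    _RC_TABLE[_f] = _r


def _revcomp_codes(read: np.ndarray) -> np.ndarray:
    return _RC_TABLE[read][::-1]


def _apply_read_errors(rng: np.random.Generator, read: np.ndarray, rate: float) -> np.ndarray:
    """Apply substitutions, insertions and deletions at 60:20:20."""
    n = read.shape[0]
    hit = rng.random(n) < rate
    positions = np.flatnonzero(hit)
    if positions.size == 0:
        return read
    kinds = rng.choice(3, size=positions.size, p=[0.6, 0.2, 0.2])  # 0 sub, 1 ins, 2 del

    sub_pos = positions[kinds == 0]
    if sub_pos.size:
        shift = rng.integers(1, 4, size=sub_pos.size)
        idx = np.searchsorted(_BASES, read[sub_pos])
        # non-ACGT bases (shouldn't occur) are left untouched by clipping
        idx = np.clip(idx, 0, 3)
        read = read.copy()
        read[sub_pos] = _BASES[(idx + shift) % 4]

    del_pos = positions[kinds == 2]
    ins_pos = positions[kinds == 1]
    ins_bases = _BASES[rng.integers(0, 4, size=ins_pos.size)]
    if del_pos.size:
        keep = np.ones(read.shape[0], dtype=bool)
        keep[del_pos] = False
        # adjust insertion positions for removed bases
        if ins_pos.size:
            ins_pos = ins_pos - np.searchsorted(del_pos, ins_pos)
        read = read[keep]
    if ins_pos.size:
        read = np.insert(read, np.minimum(ins_pos, read.shape[0]), ins_bases)
    return read
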