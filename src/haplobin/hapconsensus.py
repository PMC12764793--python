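"""Haplotype consensus: phased VCF + reference -> two haplotype sequences.

Given a haploid reference and phased heterozygous variants, substitute each
site's haplotype-1 or haplotype-2 allele into the reference to obtain the
two consensus haplotype sequences that feed haplotype-specific k-mer
extraction. Variant records are filtered on site mapping quality and depth
before application; only biallelic heterozygous records are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedVariant",
    "read_phased_vcf",
    "select_heterozygous",
    "apply_haplotype",
    "consensus_haplotypes",
    "roundtrip_check",
    "RoundtripReport",
]


@dataclass(frozen=True)
class PhasedVariant:
    """One phased heterozygous site.

    ``pos`` is the 1-based reference position (VCF convention). ``phase``
    is the ordered allele-index pair (haplotype 1, haplotype 2): (0, 1)
    means haplotype 1 carries REF. ``phase_set`` identifies the phase
    block. ``mapq``/``depth`` are site annotations used for filtering and
    may be None when the source VCF lacks them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    phase: tuple[int, int]
    phase_set: str
    mapq: float | None = None
    depth: float | None = None

    def allele(self, haplotype_index: int) -> str:
        if haplotype_index not in (1, 2):
            raise ValueError("haplotype_index must be 1 or 2")
        return self.alt if self.phase[haplotype_index - 1] == 1 else self.ref

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def flipped(self) -> "PhasedVariant":
        return PhasedVariant(
            self.chrom, self.pos, self.ref, self.alt,
            (self.phase[1], self.phase[0]), self.phase_set, self.mapq, self.depth,
        )


def read_phased_vcf(path) -> list[PhasedVariant]:
    """Load phased records from a VCF (single sample, GT with '|', PS tag).

    Unphased or non-diploid genotypes are skipped with a warning;
    multiallelic records are kept here (ALT joined) and rejected later by
    :func:`select_heterozygous`. MQ and DP are taken from INFO when
    present, falling back to the sample's FORMAT/DP.
    """
    from cyvcf2 import VCF

    records: list[PhasedVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            gts = rec.genotypes
            if not gts:
                continue
            g = gts[0]  # [allele1, allele2, phased]
            if len(g) != 3:
                logger.warning("skipping non-diploid genotype at %s:%s", rec.CHROM, rec.POS)
                continue
            a1, a2, phased = g
            if not phased and a1 != a2:
                logger.warning("skipping unphased heterozygote at %s:%s", rec.CHROM, rec.POS)
                continue
            ps = rec.format("PS")
            phase_set = str(int(ps[0][0])) if ps is not None else "."
            mq = rec.INFO.get("MQ")
            dp = rec.INFO.get("DP")
            if dp is None:
                fmt_dp = rec.format("DP")
                if fmt_dp is not None:
                    dp = float(fmt_dp[0][0])
            records.append(
                PhasedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=",".join(rec.ALT),
                    phase=(int(a1), int(a2)),
                    phase_set=phase_set,
                    mapq=float(mq) if mq is not None else None,
                    depth=float(dp) if dp is not None else None,
                )
            )
    finally:
        vcf.close()
    return records


def select_heterozygous(
    variants: Iterable[PhasedVariant],
    min_mapq: float = 20,
    min_depth: float = 10,
) -> list[PhasedVariant]:
    """Keep biallelic heterozygous records with MQ >= min_mapq and DP >= min_depth.

    Both thresholds are inclusive. Records missing either annotation are
    rejected with a logged warning rather than raising. Order is preserved.
    """
    kept: list[PhasedVariant] = []
    for v in variants:
        if v.phase not in ((0, 1), (1, 0)):
            continue  # homozygous or non-standard
        if "," in v.alt:
            continue  # multiallelic
        if v.ref == v.alt:
            continue
        if v.mapq is None or v.depth is None:
            logger.warning(
                "rejecting %s:%s: missing %s annotation",
                v.chrom, v.pos, "MQ" if v.mapq is None else "DP",
            )
            continue
        if v.mapq >= min_mapq and v.depth >= min_depth:
            kept.append(v)
    return kept


def apply_haplotype(
    reference: dict[str, str],
    variants: Sequence[PhasedVariant],
    haplotype_index: int,
) -> dict[str, str]:
    """Substitute each variant's chosen-haplotype allele into the reference.

    Variants must be sorted by position within each chromosome and their
    reference spans must not overlap; each REF allele is checked against
    the reference sequence. Indel coordinate shifts are handled by applying
    substitutions left to right.
    """
    if haplotype_index not in (1, 2):
        raise ValueError("haplotype_index must be 1 or 2")
    by_chrom: dict[str, list[PhasedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    out: dict[str, str] = {}
    for chrom, seq in reference.items():
        vs = by_chrom.get(chrom, [])
        parts: list[str] = []
        cursor = 0
        prev_end = -1
        prev_pos = None
        for v in vs:
            p0 = v.pos - 1
            if p0 < prev_end:
                raise ValueError(
                    f"overlapping variants at {chrom}:{prev_pos} and {chrom}:{v.pos}"
                )
            observed = seq[p0 : p0 + len(v.ref)]
            if observed != v.ref:
                raise ValueError(
                    f"REF allele mismatch at {chrom}:{v.pos}: "
                    f"VCF says {v.ref!r}, reference has {observed!r}"
                )
            parts.append(seq[cursor:p0])
            parts.append(v.allele(haplotype_index))
            cursor = p0 + len(v.ref)
            prev_end = cursor
            prev_pos = v.pos
        parts.append(seq[cursor:])
        out[chrom] = "".join(parts)
    return out


def consensus_haplotypes(
    reference: dict[str, str],
    variants: Sequence[PhasedVariant],
    designated_phase_sets: dict[str, str] | None = None,
) -> tuple[dict[str, str], dict[str, str], int]:
    """Build both haplotype sequences, optionally restricted to one phase set.

    ``designated_phase_sets`` maps chromosome -> phase-set id (typically the
    chromosome-level block); records in other phase sets are skipped and
    their count returned, since residual small blocks cannot be integrated
    into the chromosome-level phase.
    """
    if designated_phase_sets is None:
        applied = list(variants)
        skipped = 0
    else:
        applied, skipped = [], 0
        for v in variants:
            if designated_phase_sets.get(v.chrom) == v.phase_set:
                applied.append(v)
            else:
                skipped += 1
    hap1 = apply_haplotype(reference, applied, 1)
    hap2 = apply_haplotype(reference, applied, 2)
    return hap1, hap2, skipped


@dataclass
class RoundtripReport:
    n_variants: int
    n_recovered: int
    discrepancies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.discrepancies and self.n_recovered == self.n_variants


def _left_normalize(ref: str, alt: str) -> tuple[str, str]:
    """Trim shared suffix then shared prefix beyond the anchor base."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0] and ref[1] == alt[1]:
        ref, alt = ref[1:], alt[1:]
    return ref, alt


def roundtrip_check(
    hap1: dict[str, str],
    hap2: dict[str, str],
    variants: Sequence[PhasedVariant],
) -> RoundtripReport:
    """Verify that the differences between two consensus haplotypes are the variants.

    SNV-only chromosomes are checked by blind position scan (every mismatch
    must be an input variant with matching alleles, and vice versa); mixed
    SNV/indel inputs are checked by a coordinate walk comparing each
    variant's alleles (after left-normalization) and the inter-variant
    segments.
    """
    by_chrom: dict[str, list[PhasedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    report = RoundtripReport(n_variants=len(variants), n_recovered=0)
    for chrom in sorted(set(hap1) | set(hap2)):
        s1, s2 = hap1.get(chrom, ""), hap2.get(chrom, "")
        vs = sorted(by_chrom.get(chrom, []), key=lambda v: v.pos)
        snv_only = all(v.is_snv for v in vs)
        if snv_only and len(s1) == len(s2):
            _scan_snvs(chrom, s1, s2, vs, report)
        else:
            _walk_mixed(chrom, s1, s2, vs, report)
    return report


def _scan_snvs(chrom, s1, s2, vs, report):
    # haplotype coordinates == reference coordinates when no indel applied
    expected = {}
    for v in vs:
        expected[v.pos - 1] = (v.allele(1), v.allele(2))
    found = set()
    for i, (a, b) in enumerate(zip(s1, s2)):
        if a == b:
            continue
        exp = expected.get(i)
        if exp is None:
            report.discrepancies.append(f"{chrom}:{i + 1}: unexpected difference {a}/{b}")
        elif exp != (a, b):
            report.discrepancies.append(
                f"{chrom}:{i + 1}: alleles {a}/{b} do not match variant {exp[0]}/{exp[1]}"
            )
        else:
            found.add(i)
            report.n_recovered += 1
    for p0 in sorted(set(expected) - found):
        report.discrepancies.append(f"{chrom}:{p0 + 1}: variant not observed in haplotypes")


def _walk_mixed(chrom, s1, s2, vs, report):
    c1 = c2 = 0
    ref_cursor = 0
    for v in vs:
        p0 = v.pos - 1
        gap = p0 - ref_cursor
        seg1, seg2 = s1[c1 : c1 + gap], s2[c2 : c2 + gap]
        if seg1 != seg2:
            report.discrepancies.append(
                f"{chrom}: inter-variant segment before {v.pos} differs between haplotypes"
            )
        c1 += gap
        c2 += gap
        a1, a2 = v.allele(1), v.allele(2)
        obs1, obs2 = s1[c1 : c1 + len(a1)], s2[c2 : c2 + len(a2)]
        n1, n2 = _left_normalize(obs1, obs2)
        e1, e2 = _left_normalize(a1, a2)
        if (n1, n2) != (e1, e2):
            report.discrepancies.append(
                f"{chrom}:{v.pos}: observed alleles {obs1}/{obs2} != expected {a1}/{a2}"
            )
        else:
            report.n_recovered += 1
        c1 += len(a1)
        c2 += len(a2)
        ref_cursor = p0 + len(v.ref)
    tail1, tail2 = s1[c1:], s2[c2:]
    if tail1 != tail2:
        report.discrepancies.append(f"{chrom}: trailing segment differs between haplotypes")
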