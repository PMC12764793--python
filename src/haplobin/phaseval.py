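"""Phasing-quality statistics.

When the individual's haplotype is known to match (or oppose) the
reference along a whole chromosome — for instance when the reference is a
doubled-haploid derivative of the sample — the fraction of phased sites at
which one haplotype carries the non-reference allele, computed in genomic
windows, reads out local phasing accuracy: it should sit near 0 or 1, and
its folded value min(r, 1 - r) near 0. The median folded window ratio over
chromosomes free of recombination and large homozygous runs estimates the
phase switch rate.

Also provided: phase-block statistics from PS tags, selection of the
longest (chromosome-level) phase block, and discordance between two
phasings of the same sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

from .hapconsensus import PhasedVariant

__all__ = [
    "WindowRatio",
    "PhaseBlock",
    "PhaseBlockStats",
    "window_nonref_ratio",
    "switch_rate",
    "phase_block_stats",
    "select_longest_block",
    "compare_phasings",
    "DiscordanceReport",
]

WINDOW_1MB = 1_000_000


@dataclass(frozen=True)
class WindowRatio:
    """Non-reference allele ratio of one haplotype in one genomic window.

    ``nonref_ratio`` is None for windows without phased sites (undefined).
    Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    nonref_ratio: float | None

    @property
    def defined(self) -> bool:
        return self.n_sites > 0


def window_nonref_ratio(
    variants: Sequence[PhasedVariant],
    haplotype_index: int = 1,
    window_size: int = WINDOW_1MB,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowRatio]:
    """Per-window fraction of sites where a haplotype carries the ALT allele.

    Windows tile each chromosome from position 0; the last window may be
    short. Without ``chrom_lengths`` the tiling extends to the last phased
    site. An unphased genotype raises.
    """
    if haplotype_index not in (1, 2):
        raise ValueError("haplotype_index must be 1 or 2")
    by_chrom: dict[str, list[PhasedVariant]] = {}
    for v in variants:
        if v.phase not in ((0, 1), (1, 0)):
            raise ValueError(f"unphased or homozygous genotype at {v.chrom}:{v.pos}")
        by_chrom.setdefault(v.chrom, []).append(v)

    out: list[WindowRatio] = []
    chroms = sorted(chrom_lengths) if chrom_lengths else sorted(by_chrom)
    for chrom in chroms:
        vs = sorted(by_chrom.get(chrom, []), key=lambda v: v.pos)
        if chrom_lengths:
            length = chrom_lengths[chrom]
        elif vs:
            length = vs[-1].pos
        else:
            continue
        n_windows = max(1, -(-length // window_size))
        counts = [0] * n_windows
        nonref = [0] * n_windows
        for v in vs:
            w = (v.pos - 1) // window_size
            counts[w] += 1
            if v.phase[haplotype_index - 1] == 1:
                nonref[w] += 1
        for w in range(n_windows):
            start = w * window_size
            end = min(start + window_size, length)
            ratio = nonref[w] / counts[w] if counts[w] else None
            out.append(WindowRatio(chrom, start, end, counts[w], ratio))
    return out


def switch_rate(
    ratios: Iterable[WindowRatio],
    chroms: Iterable[str] | None = None,
    fold: bool = True,
) -> float:
    """Median window non-reference ratio: the phase-switch-rate estimate.

    With ``fold`` (default) each ratio r contributes min(r, 1 - r), making
    the estimate invariant to which haplotype matches the reference and to
    global phase flips. Undefined (empty) windows are excluded rather than
    imputed, since switches concentrate in low-SNP-density regions and
    imputation would bias the median. Restrict ``chroms`` to chromosomes
    without recombination or long homozygous runs.
    """
    wanted = set(chroms) if chroms is not None else None
    values = [
        min(w.nonref_ratio, 1 - w.nonref_ratio) if fold else w.nonref_ratio
        for w in ratios
        if w.defined and (wanted is None or w.chrom in wanted)
    ]
    if not values:
        raise ValueError("no defined windows on the selected chromosomes")
    return float(median(values))


@dataclass(frozen=True)
class PhaseBlock:
    chrom: str
    phase_set: str
    first_pos: int
    last_pos: int
    n_sites: int

    @property
    def span(self) -> int:
        return self.last_pos - self.first_pos


@dataclass(frozen=True)
class PhaseBlockStats:
    blocks: tuple[PhaseBlock, ...]
    per_chrom: dict[str, dict]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def phase_block_stats(variants: Sequence[PhasedVariant]) -> PhaseBlockStats:
    """Group phased sites into blocks by phase-set tag and summarise.

    Per chromosome: block count, largest block span, and the fraction of
    phased sites falling in the largest block.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for v in variants:
        groups.setdefault((v.chrom, v.phase_set), []).append(v.pos)

    blocks = tuple(
        PhaseBlock(chrom, ps, min(pos), max(pos), len(pos))
        for (chrom, ps), pos in sorted(groups.items())
    )
    per_chrom: dict[str, dict] = {}
    for chrom in sorted({b.chrom for b in blocks}):
        cb = [b for b in blocks if b.chrom == chrom]
        total_sites = sum(b.n_sites for b in cb)
        largest = max(cb, key=lambda b: (b.span, b.n_sites))
        per_chrom[chrom] = {
            "n_blocks": len(cb),
            "largest_span": largest.span,
            "largest_block_site_fraction": largest.n_sites / total_sites,
        }
    return PhaseBlockStats(blocks, per_chrom)


def select_longest_block(variants: Sequence[PhasedVariant]) -> list[PhasedVariant]:
    """Keep only sites of the greatest-span phase block on each chromosome.

    Ties on span are broken by site count, then by smallest phase-set id.
    """
    stats = phase_block_stats(variants)
    chosen: dict[str, str] = {}
    for chrom in {b.chrom for b in stats.blocks}:
        cb = [b for b in stats.blocks if b.chrom == chrom]
        best = max(cb, key=lambda b: (b.span, b.n_sites, -_ps_sort_key(b.phase_set)))
        chosen[chrom] = best.phase_set
    return [v for v in variants if chosen.get(v.chrom) == v.phase_set]


def _ps_sort_key(ps: str) -> float:
    try:
        return float(ps)
    except ValueError:
        return float("inf")


@dataclass(frozen=True)
class DiscordanceReport:
    n_shared: int
    n_discordant: int
    per_window: dict[tuple[str, int], int]
    orientation: dict[str, bool]  # chrom -> b was globally flipped

    @property
    def percent(self) -> float:
        return 100.0 * self.n_discordant / self.n_shared


def compare_phasings(
    variants_a: Sequence[PhasedVariant],
    variants_b: Sequence[PhasedVariant],
    window_size: int = WINDOW_1MB,
) -> DiscordanceReport:
    """Count sites phased differently by two phasings of the same reference.

    Sites are matched by (chrom, pos, ref, alt). Because the labels
    "haplotype 1"/"haplotype 2" are arbitrary, phasing b is first oriented
    per chromosome to the orientation (flipped or not) minimising
    mismatches; the discordant count is then the number of matched sites
    whose haplotype-1 allele still differs.
    """
    index_b = {(v.chrom, v.pos, v.ref, v.alt): v for v in variants_b}
    matched: dict[str, list[tuple[PhasedVariant, PhasedVariant]]] = {}
    for va in variants_a:
        vb = index_b.get((va.chrom, va.pos, va.ref, va.alt))
        if vb is not None:
            matched.setdefault(va.chrom, []).append((va, vb))
    n_shared = sum(len(pairs) for pairs in matched.values())
    if n_shared == 0:
        raise ValueError("the two phasings share no sites")

    per_window: dict[tuple[str, int], int] = {}
    orientation: dict[str, bool] = {}
    n_discordant = 0
    for chrom, pairs in sorted(matched.items()):
        direct = sum(1 for a, b in pairs if a.phase != b.phase)
        flipped = len(pairs) - direct
        flip = flipped < direct
        orientation[chrom] = flip
        for a, b in pairs:
            phase_b = (b.phase[1], b.phase[0]) if flip else b.phase
            if a.phase != phase_b:
                n_discordant += 1
                w = (a.pos - 1) // window_size
                per_window[(chrom, w)] = per_window.get((chrom, w), 0) + 1
    return DiscordanceReport(n_shared, n_discordant, per_window, orientation)
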