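"""Simulator properties: determinism, rate calibration, truth consistency."""

import numpy as np
import pytest

from haplobin import simdip
from haplobin.kmerlib import reverse_complement


def _cfg(**kw):
    defaults = dict(n_chromosomes=1, chrom_length=50_000, snv_rate=0.0,
                    indel_rate=0.0, pav_rate=0.0, seed=3)
    defaults.update(kw)
    return simdip.DiploidSimConfig(**defaults)


def test_all_rates_zero_gives_identical_haplotypes():
    h1, h2, truth = simdip.simulate_diploid(_cfg())
    assert h1 == h2
    assert truth.variants == []


def test_snv_count_within_binomial_tolerance():
    """At 1 SNV per 20 bp over 100 kb, ~5000 sites within 3 binomial SD."""
    cfg = _cfg(chrom_length=100_000, snv_rate=0.05, seed=5)
    _, _, truth = simdip.simulate_diploid(cfg)
    n = len(truth.variants)
    expected = 5000
    sd = np.sqrt(100_000 * 0.05 * 0.95)
    assert abs(n - expected) <= 3 * sd


def test_same_seed_identical_output():
    cfg = _cfg(snv_rate=0.02, indel_rate=0.001, pav_rate=2e-5, seed=9)
    out1 = simdip.simulate_diploid(cfg)
    out2 = simdip.simulate_diploid(cfg)
    assert out1[0] == out2[0] and out1[1] == out2[1]
    assert out1[2].variants == out2[2].variants


def test_different_seed_differs():
    a = simdip.simulate_diploid(_cfg(snv_rate=0.01, seed=1))
    b = simdip.simulate_diploid(_cfg(snv_rate=0.01, seed=2))
    assert a[0] != b[0]


def test_variant_classes_respect_sv_cutoff(mixed_diploid):
    _, _, _, truth = mixed_diploid
    for v in truth.variants:
        event = abs(len(v.alt) - len(v.ref))
        if v.vclass == simdip.SNV:
            assert len(v.ref) == len(v.alt) == 1
        elif v.vclass == simdip.INDEL:
            assert 1 <= event < 50
        else:
            assert event >= 50


def test_hap2_sequence_matches_applied_variants(mixed_diploid):
    """Exact comparison of hap1 vs hap2 recovers the variant alleles."""
    _, hap1, hap2, truth = mixed_diploid
    for chrom in hap1:
        vs = truth.variants_for(chrom)
        offset = 0
        for v in vs:
            p2 = v.pos + offset
            assert hap2[chrom][p2 : p2 + len(v.alt)] == v.alt
            assert hap1[chrom][v.pos : v.pos + len(v.ref)] == v.ref
            offset += len(v.alt) - len(v.ref)
        assert len(hap2[chrom]) == len(hap1[chrom]) + offset


def test_planted_repeats_in_both_haplotypes():
    cfg = _cfg(repeat_fraction=0.1, snv_rate=0.0, seed=13)
    h1, h2, truth = simdip.simulate_diploid(cfg)
    assert truth.repeat_intervals
    chrom, s, e = truth.repeat_intervals[0]
    unit = h1[chrom][s:e]
    for c, s2, e2 in truth.repeat_intervals:
        assert h1[c][s2:e2] == unit
        assert unit in h2[c]


def test_pav_too_long_for_chromosome_rejected():
    with pytest.raises(ValueError, match="too short"):
        simdip.DiploidSimConfig(
            n_chromosomes=1, chrom_length=100, pav_rate=0.01,
            pav_len_range=(99, 200),
        ).validate()


class TestMosaicReference:
    def test_zero_switches_returns_hap1(self, small_diploid):
        _, h1, h2, truth = small_diploid
        ref, t2 = simdip.make_mosaic_reference(h1, h2, truth, 0, seed=1)
        assert ref == h1
        assert all(b.source_hap == 1 for b in t2.mosaic_blocks)

    def test_one_switch_two_blocks_per_chrom(self, small_diploid):
        _, h1, h2, truth = small_diploid
        _, t2 = simdip.make_mosaic_reference(h1, h2, truth, 1, seed=1)
        for chrom in h1:
            blocks = [b for b in t2.mosaic_blocks if b.chrom == chrom]
            assert len(blocks) == 2
            assert [b.source_hap for b in blocks] == [1, 2]

    def test_boundaries_never_split_a_variant(self, mixed_diploid):
        _, h1, h2, truth = mixed_diploid
        _, t2 = simdip.make_mosaic_reference(h1, h2, truth, 3, seed=2)
        for b in t2.mosaic_blocks:
            for v in truth.variants_for(b.chrom):
                s, e = v.ref_span
                # a boundary strictly inside the ref span would split the allele
                assert not (s < b.hap1_start < e)

    def test_blocks_tile_reference(self, mixed_diploid):
        _, h1, h2, truth = mixed_diploid
        ref, t2 = simdip.make_mosaic_reference(h1, h2, truth, 2, seed=3)
        for chrom in ref:
            blocks = [b for b in t2.mosaic_blocks if b.chrom == chrom]
            assert blocks[0].start == 0
            assert blocks[-1].end == len(ref[chrom])
            for a, b in zip(blocks, blocks[1:]):
                assert a.end == b.start


class TestEmitPhasedVcf:
    def test_no_errors_truth_orientation(self, small_diploid):
        _, h1, _, truth = small_diploid
        records, t2 = simdip.emit_phased_vcf(truth, h1, 0.0, seed=1)
        assert len(records) == len(truth.variants)
        assert all(r.phase == (0, 1) for r in records)
        assert t2.switch_points == []

    def test_rate_one_flips_everything(self, small_diploid):
        _, h1, _, truth = small_diploid
        records, t2 = simdip.emit_phased_vcf(truth, h1, 1.0, seed=1)
        assert all(r.phase == (1, 0) for r in records)
        assert len(t2.switch_points) == len(records)

    def test_flip_fraction_binomial(self, small_diploid):
        _, h1, _, truth = small_diploid
        rate = 0.02
        records, t2 = simdip.emit_phased_vcf(truth, h1, rate, seed=4)
        n = len(records)
        assert n >= 5000
        frac = len(t2.switch_points) / n
        sd = np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) <= 3 * sd

    def test_one_phase_set_per_chromosome(self, small_diploid):
        _, h1, _, truth = small_diploid
        records, _ = simdip.emit_phased_vcf(truth, h1, 0.0, seed=1)
        for chrom in h1:
            assert len({r.phase_set for r in records if r.chrom == chrom}) == 1

    def test_mosaic_reference_alleles_verified(self, small_diploid):
        """Emission against a mosaic checks REF alleles against the sequence."""
        _, h1, h2, truth = small_diploid
        ref, t2 = simdip.make_mosaic_reference(h1, h2, truth, 2, seed=8)
        records, _ = simdip.emit_phased_vcf(t2, ref, 0.0, seed=1)
        # inside hap2-sourced blocks haplotype 1 carries the ALT allele
        by_block = {(b.start, b.end): b for b in t2.mosaic_blocks}
        for r in records:
            blk = next(b for b in t2.mosaic_blocks
                       if b.chrom == r.chrom and b.start <= r.pos - 1 < b.end)
            expected = (0, 1) if blk.source_hap == 1 else (1, 0)
            assert r.phase == expected

    def test_vcf_file_roundtrip(self, small_diploid, tmp_path):
        from haplobin import hapconsensus
        _, h1, _, truth = small_diploid
        records, _ = simdip.emit_phased_vcf(truth, h1, 0.0, seed=1)
        path = tmp_path / "phased.vcf"
        simdip.write_vcf(records, h1, path)
        loaded = hapconsensus.read_phased_vcf(path)
        assert [(v.chrom, v.pos, v.ref, v.alt, v.phase) for v in loaded] == \
               [(v.chrom, v.pos, v.ref, v.alt, v.phase) for v in records]
        assert all(v.mapq == 60 and v.depth == 30 for v in loaded)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, small_diploid):
        _, h1, h2, _ = small_diploid
        reads, labels = simdip.simulate_reads(
            (h1, h2), read_length_mean=2000, read_length_min=500,
            n_reads=40, error_rate=0.0, seed=6)
        haps = {1: h1, 2: h2}
        for rec in reads:
            source = haps[labels[rec.id]]
            found = any(
                rec.sequence in seq or reverse_complement(rec.sequence) in seq
                for seq in source.values()
            )
            assert found, rec.id

    def test_every_read_labelled_once(self, small_diploid):
        _, h1, h2, _ = small_diploid
        reads, labels = simdip.simulate_reads(
            (h1, h2), read_length_mean=1000, read_length_min=500,
            n_reads=100, seed=6)
        assert sorted(labels) == sorted(r.id for r in reads)
        assert len(reads) == 100

    def test_depth_targets_total_bases(self, small_diploid):
        _, h1, h2, _ = small_diploid
        depth = 3.0
        reads, _ = simdip.simulate_reads(
            (h1, h2), read_length_mean=2000, read_length_min=500,
            depth=depth, seed=6)
        genome = sum(len(s) for s in h1.values()) + sum(len(s) for s in h2.values())
        total = sum(len(r.sequence) for r in reads)
        assert abs(total - depth * genome) <= 0.05 * depth * genome

    def test_seeds_differ(self, small_diploid):
        _, h1, h2, _ = small_diploid
        a, _ = simdip.simulate_reads((h1, h2), read_length_mean=1000,
                                     read_length_min=500, n_reads=10, seed=1)
        b, _ = simdip.simulate_reads((h1, h2), read_length_mean=1000,
                                     read_length_min=500, n_reads=10, seed=2)
        assert [r.sequence for r in a] != [r.sequence for r in b]

    def test_strand_balance(self, small_diploid):
        """Roughly half the error-free reads align to the reverse strand."""
        _, h1, h2, _ = small_diploid
        reads, labels = simdip.simulate_reads(
            (h1, h2), read_length_mean=1000, read_length_min=500,
            n_reads=400, error_rate=0.0, seed=17)
        haps = {1: h1, 2: h2}
        n_rev = 0
        for rec in reads:
            source = haps[labels[rec.id]]
            if not any(rec.sequence in seq for seq in source.values()):
                n_rev += 1
        sd = np.sqrt(400 * 0.25)
        assert abs(n_rev - 200) <= 3 * sd

    def test_min_length_exceeding_chromosome_raises(self, small_diploid):
        _, h1, h2, _ = small_diploid
        with pytest.raises(ValueError, match="exceeds"):
            simdip.simulate_reads((h1, h2), read_length_mean=100_000,
                                  read_length_min=100_000, n_reads=1, seed=1)

    def test_error_rate_changes_reads(self, small_diploid):
        _, h1, h2, _ = small_diploid
        clean, labels = simdip.simulate_reads(
            (h1, h2), read_length_mean=2000, read_length_min=1000,
            n_reads=20, error_rate=0.1, seed=3)
        haps = {1: h1, 2: h2}
        exact = sum(
            any(rec.sequence in seq for seq in haps[labels[rec.id]].values())
            for rec in clean
        )
        assert exact == 0  # 10% error leaves no read intact
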