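"""K-mer coverage, repeat masking, alignment filtering and CIGAR parsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplobin import hapcompare
from haplobin.hapcompare import AlignmentRecord

from oracles import expand_cigar_breakdown, random_sequence


def aln(cigar, query="q", target="t", mapq=60, primary=True, qlen=None,
        qstart=0, qend=None):
    if qend is None:
        # derive query span from the CIGAR's query-consuming ops
        import re
        qend = qstart + sum(int(n) for n, op in re.findall(r"(\d+)([MIDSHX=])", cigar)
                            if op in "MIS=X")
    if qlen is None:
        qlen = qend
    return AlignmentRecord(query, qlen, qstart, qend, target, 0, 0,
                           "+", mapq, primary, cigar)


class TestCigarParsing:
    @pytest.mark.parametrize(
        "cigar, match, snv, pav_count, pav_len, sc, total, identity",
        [
            ("10=1X9=", 19, 1, 0, 0, 0, 20, 0.95),
            ("20=60I20=", 40, 0, 1, 60, 0, 100, 0.40),
            ("5S20=", 20, 0, 0, 0, 5, 25, 0.80),
            ("55S20=", 20, 0, 1, 55, 55, 75, 20 / 75),
        ],
    )
    def test_hand_worked_examples(self, cigar, match, snv, pav_count, pav_len,
                                  sc, total, identity):
        b = hapcompare.parse_cigar_variation(cigar)
        assert b.match_len == match
        assert b.snv_count == snv
        assert b.pav_count == pav_count
        assert b.pav_len == pav_len
        assert b.sc_len == sc
        assert b.total_len == total
        assert b.identity == pytest.approx(identity)

    def test_indel_below_cutoff(self):
        b = hapcompare.parse_cigar_variation("10=49D10=")
        assert b.indel_count == 1 and b.indel_len == 49 and b.pav_count == 0

    def test_indel_at_cutoff_is_pav(self):
        b = hapcompare.parse_cigar_variation("10=50D10=")
        assert b.pav_count == 1 and b.pav_len == 50 and b.indel_count == 0

    def test_ambiguous_m_raises(self):
        with pytest.raises(ValueError, match="eqx"):
            hapcompare.parse_cigar_variation("10M")

    def test_hard_clips_ignored(self):
        a = hapcompare.parse_cigar_variation("5H10=5H")
        b = hapcompare.parse_cigar_variation("10=")
        assert a == b

    @given(st.lists(
        st.tuples(st.integers(1, 120), st.sampled_from("=XIDS")),
        min_size=1, max_size=12))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_expansion_oracle_and_conserves_bases(self, ops):
        cigar = "".join(f"{n}{op}" for n, op in ops)
        b = hapcompare.parse_cigar_variation(cigar)
        o = expand_cigar_breakdown(cigar)
        assert b.match_len == o["match"]
        assert b.snv_len == o["snv_len"]
        assert b.indel_count == o["indel_count"]
        assert b.indel_len == o["indel_len"]
        assert b.pav_count == o["pav_count"]
        assert b.pav_len == o["pav_len"]
        assert b.sc_len == o["sc"]
        assert b.total_len == o["total"]
        # conservation: the five categories sum to the total exactly
        assert (b.match_len + b.snv_len + b.indel_len
                + b.pav_internal_len + b.sc_len) == b.total_len
        if b.total_len:
            assert b.identity == pytest.approx(b.match_len / b.total_len)


class TestFilterAlignments:
    def test_synteny_preset_inclusive(self):
        keep = aln("2000=", mapq=60)
        assert hapcompare.filter_alignments([keep], preset="synteny") == [keep]

    def test_synteny_preset_rejects_below(self):
        assert hapcompare.filter_alignments([aln("2000=", mapq=59)], preset="synteny") == []
        assert hapcompare.filter_alignments([aln("1999=", mapq=60)], preset="synteny") == []

    def test_dotplot_mq_zero_removed(self):
        assert hapcompare.filter_alignments([aln("2000=", mapq=0)], preset="dotplot") == []
        kept = hapcompare.filter_alignments([aln("2000=", mapq=1)], preset="dotplot")
        assert len(kept) == 1

    def test_unitig_preset_boundaries(self):
        assert len(hapcompare.filter_alignments([aln("100=", mapq=50)], preset="unitig")) == 1
        assert hapcompare.filter_alignments([aln("99=", mapq=50)], preset="unitig") == []
        assert hapcompare.filter_alignments([aln("100=", mapq=49)], preset="unitig") == []

    def test_secondary_removed_by_default(self):
        sec = aln("5000=", mapq=60, primary=False)
        assert hapcompare.filter_alignments([sec], preset="synteny") == []
        assert hapcompare.filter_alignments([sec], preset="synteny",
                                            primary_only=False) == [sec]

    def test_matches_brute_force(self, rng):
        records = [aln(f"{int(rng.integers(1, 5000))}=",
                       mapq=int(rng.integers(0, 61)),
                       primary=bool(rng.random() < 0.8))
                   for _ in range(200)]
        out = hapcompare.filter_alignments(records, min_len=2000, min_mapq=60)
        brute = [r for r in records
                 if r.primary and r.query_span >= 2000 and r.mapq >= 60]
        assert out == brute


class TestKmerCoverage:
    def test_self_unique_coverage_one(self, rng):
        seq = random_sequence(rng, 300)
        cov = hapcompare.kmer_position_coverage({"c": seq}, {"c": seq}, k=27)["c"]
        assert (cov == 1).all()

    def test_empty_source_zero(self, rng):
        seq = random_sequence(rng, 100)
        cov = hapcompare.kmer_position_coverage({"c": seq}, {}, k=27)["c"]
        assert (cov == 0).all()

    def test_duplicated_segment_coverage_two(self, rng):
        k = 27
        segment = random_sequence(rng, 200)
        source = {"s": random_sequence(rng, 300) + segment
                  + random_sequence(rng, 300) + segment + random_sequence(rng, 100)}
        target = {"t": random_sequence(rng, 150) + segment + random_sequence(rng, 150)}
        cov = hapcompare.kmer_position_coverage(target, source, k)["t"]
        inner = cov[150 : 150 + 200 - k + 1]  # k-mer starts fully inside the segment
        assert (inner >= 2).all()

    def test_n_positions_zero(self):
        cov = hapcompare.kmer_position_coverage(
            {"c": "ACGTNACGT"}, {"c": "ACGTACGT"}, k=3)["c"]
        assert cov[4] == 0

    def test_trailing_positions_inherit_last_start(self, rng):
        seq = random_sequence(rng, 100)
        cov = hapcompare.kmer_position_coverage({"c": seq}, {"c": seq}, k=27)["c"]
        assert (cov[-26:] == cov[100 - 27]).all()


class TestMaskRepetitive:
    def test_below_threshold_untouched(self, rng):
        seq = random_sequence(rng, 200)
        cov = {"c": np.ones(200, dtype=np.int64)}
        masked, rep, nonrep = hapcompare.mask_repetitive({"c": seq}, cov)
        assert masked["c"] == seq
        assert rep == []
        assert nonrep == [("c", 0, 200)]

    def test_fully_repetitive_fully_masked(self):
        cov = {"c": np.full(50, 3, dtype=np.int64)}
        masked, rep, nonrep = hapcompare.mask_repetitive({"c": "A" * 50}, cov)
        assert masked["c"] == "N" * 50
        assert rep == [("c", 0, 50)] and nonrep == []

    def test_planted_repeat_masked_within_k_minus_1(self, rng):
        k = 27
        unit = random_sequence(rng, 200)
        seq = random_sequence(rng, 300) + unit + random_sequence(rng, 300) \
            + unit + random_sequence(rng, 100)
        cov = hapcompare.kmer_position_coverage({"c": seq}, {"c": seq}, k)
        masked, rep, _ = hapcompare.mask_repetitive({"c": seq}, cov)
        merged = [iv for iv in rep if iv[1] - iv[2] != 0]
        for start in (300, 800):
            span = [iv for iv in rep if iv[1] >= start - k and iv[2] <= start + 200 + k]
            assert span, f"no masked run near planted copy at {start}"
            s, e = span[0][1], span[-1][2]
            assert abs(s - start) <= k - 1
            assert abs(e - (start + 200)) <= k - 1

    def test_idempotent(self, rng):
        seq = random_sequence(rng, 200)
        cov = {"c": (rng.integers(0, 4, 200)).astype(np.int64)}
        once, rep1, non1 = hapcompare.mask_repetitive({"c": seq}, cov)
        twice, rep2, non2 = hapcompare.mask_repetitive(once, cov)
        assert once == twice and rep1 == rep2

    def test_extract_interval_ids(self):
        seqs = {"c": "ACGTACGT"}
        out = hapcompare.extract_intervals(seqs, [("c", 2, 6)])
        assert out == {"c:2-6": "GTAC"}


class TestWindowedCoverage:
    def test_fully_nonrepetitive(self):
        df = hapcompare.windowed_category_coverage(
            [], [("c", 0, 3_000_000)], {"c": 3_000_000})
        assert (df["repetitive"] == 0).all()
        assert df["nonrepetitive"].sum() == 3_000_000

    def test_hand_built_counts(self):
        rep = [("c", 500_000, 1_500_000)]
        nonrep = [("c", 0, 500_000), ("c", 1_500_000, 2_200_000)]
        df = hapcompare.windowed_category_coverage(rep, nonrep, {"c": 3_000_000})
        assert list(df["repetitive"]) == [500_000, 500_000, 0]
        assert list(df["nonrepetitive"]) == [500_000, 500_000, 200_000]
        assert list(df["n_bases"]) == [0, 0, 800_000]

    def test_conservation_on_random_fixtures(self, rng):
        L = 500_000
        cov = rng.integers(0, 3, L).astype(np.int64)
        seq = random_sequence(rng, L)
        masked, rep, nonrep = hapcompare.mask_repetitive({"c": seq}, {"c": cov})
        df = hapcompare.windowed_category_coverage(rep, nonrep, {"c": L}, 100_000)
        assert ((df["repetitive"] + df["nonrepetitive"] + df["n_bases"])
                == (df["end"] - df["start"])).all()

    def test_overlapping_beds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            hapcompare.windowed_category_coverage(
                [("c", 0, 100)], [("c", 50, 150)], {"c": 200})


class TestIdentitySummary:
    def test_single_alignment_median(self):
        b = hapcompare.parse_cigar_variation("10=1X9=")
        table = hapcompare.identity_summary([b])
        assert table.loc["all", "median_identity"] == pytest.approx(0.95)

    def test_median_of_three(self):
        bs = [hapcompare.parse_cigar_variation(c)
              for c in ("9=1X", "8=2X", "10=")]  # identities 0.9, 0.8, 1.0
        table = hapcompare.identity_summary(bs)
        assert table.loc["all", "median_identity"] == pytest.approx(0.9)

    def test_pav_rich_lowers_identity(self):
        clean = [hapcompare.parse_cigar_variation("1000=")] * 5
        pav_rich = [hapcompare.parse_cigar_variation("500=100I400=")] * 5
        t = hapcompare.identity_summary(clean + pav_rich,
                                        ["clean"] * 5 + ["pav"] * 5)
        assert t.loc["pav", "median_identity"] < t.loc["clean", "median_identity"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hapcompare.identity_summary([])


def test_paf_roundtrip(tmp_path):
    line = ("q\t100\t0\t100\t+\tt\t500\t50\t150\t95\t100\t60\t"
            "tp:A:P\tcg:Z:95=5X\n"
            "q2\t80\t0\t80\t-\tt\t500\t0\t80\t70\t80\t0\ttp:A:S\tcg:Z:80=\n")
    p = tmp_path / "a.paf"
    p.write_text(line)
    recs = hapcompare.read_paf_alignments(p)
    assert len(recs) == 2
    assert recs[0].cigar == "95=5X" and recs[0].primary
    assert not recs[1].primary and recs[1].mapq == 0
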