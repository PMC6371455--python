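"""Feature extraction: contexts, k-mers, PWMs, methylation encoding."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scsplice import features as feat
from scsplice.types import CONTEXT_KEYS, CassetteExon, reverse_complement


def make_exon(i1_len=800, i2_len=800, a_len=100, strand="+"):
    c1 = (1000, 1200)
    a = (c1[1] + i1_len, c1[1] + i1_len + a_len)
    c2 = (a[1] + i2_len, a[1] + i2_len + 200)
    if strand == "-":
        # mirror into minus-strand transcript order: C1 genomically rightmost
        return CassetteExon(exon_id="m", chrom="chr1", strand="-",
                            c1=c2, a=a, c2=c1,
                            distance_to_tss=600, distance_to_tts=600)
    return CassetteExon(exon_id="p", chrom="chr1", strand="+", c1=c1, a=a,
                        c2=c2, distance_to_tss=600, distance_to_tts=600)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    return {"chr1": "".join(bases[rng.integers(0, 4, 6000)])}


class TestContexts:
    def test_long_intron_contexts_disjoint(self, genome):
        ctx = feat.extract_contexts(make_exon(i1_len=800), genome)
        assert len(ctx["I1_5p"]) == 300 and len(ctx["I1_3p"]) == 300
        i5 = set(ctx.positions["I1_5p"])
        i3 = set(ctx.positions["I1_3p"])
        assert not i5 & i3

    def test_short_intron_contexts_overlap_by_200(self, genome):
        ctx = feat.extract_contexts(make_exon(i1_len=400), genome)
        assert len(ctx["I1_5p"]) == 300 and len(ctx["I1_3p"]) == 300
        overlap = set(ctx.positions["I1_5p"]) & set(ctx.positions["I1_3p"])
        assert len(overlap) == 200

    def test_minus_strand_is_reverse_complement_of_mirror(self, genome):
        plus = feat.extract_contexts(make_exon(strand="+"), genome)
        minus = feat.extract_contexts(make_exon(strand="-"), genome)
        # the minus-strand exon occupies the same genomic intervals; each
        # context reads as the reverse complement of its mirror context
        mirror = {"C1": "C2", "C2": "C1", "A": "A", "I1_5p": "I2_3p",
                  "I2_3p": "I1_5p", "I1_3p": "I2_5p", "I2_5p": "I1_3p"}
        for key, mkey in mirror.items():
            assert minus[key] == reverse_complement(plus[mkey])

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            feat.extract_contexts(make_exon(), {"chr1": "ACGT" * 100})


class TestKmers:
    def test_uniform_single_bases(self):
        freqs = feat.kmer_frequencies("ACGT", k_max=1)
        assert np.allclose(freqs, 0.25)

    def test_homopolymer_dimers(self):
        freqs = feat.kmer_frequencies("AAAA", k_max=2)
        assert freqs["AA"] == 1.0
        assert freqs.drop(["A", "AA"]).eq(0).all()

    def test_each_k_block_sums_to_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        freqs = feat.kmer_frequencies(seq, k_max=3)
        for k in (1, 2, 3):
            block = [f for f in freqs.index if len(f) == k]
            assert freqs[block].sum() == pytest.approx(1.0)

    def test_n_windows_excluded_from_both_sides(self):
        # "ANAA": k=2 windows AN, NA excluded; only AA remains valid
        freqs = feat.kmer_frequencies("ANAA", k_max=2)
        assert freqs["AA"] == 1.0
        assert freqs["A"] == 1.0  # 3 valid of 3 non-N single bases

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            feat.kmer_frequencies("")

    def test_mu_kmer_count_matches_brute_force(self):
        """#{k<=3 over AGTMU containing M or U} = 116 by enumeration."""
        brute = [
            "".join(t)
            for k in (1, 2, 3)
            for t in itertools.product("AGTMU", repeat=k)
            if "M" in t or "U" in t
        ]
        assert len(brute) == (5 + 25 + 125) - (3 + 9 + 27) == 116
        assert sorted(feat.MU_KMER_NAMES) == sorted(brute)


class TestSpliceSitePwm:
    def test_consensus_scores_maximal(self):
        pwm = feat.DEFAULT_DONOR_PWM
        cons = pwm.consensus()
        best = pwm.score(cons)
        rng = np.random.default_rng(1)
        for _ in range(50):
            other = "".join(np.array(list("ACGT"))[rng.integers(0, 4, pwm.width)])
            assert pwm.score(other) <= best + 1e-12

    def test_uniform_pwm_scores_zero(self):
        pwm = feat.SpliceSitePwm(probs=np.full((4, 4), 0.25), exonic=2)
        assert pwm.score("ACGT") == pytest.approx(0.0)

    def test_hand_computed_three_column_pwm(self):
        probs = np.full((3, 4), 0.1)
        probs[:, 0] = 0.7  # consensus AAA
        pwm = feat.SpliceSitePwm(probs=probs, exonic=1)
        assert pwm.score("AAA") == pytest.approx(3 * np.log2(0.7 / 0.25), abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            feat.DEFAULT_DONOR_PWM.score("ACG")


class TestGenomicFeatures:
    def test_width_is_607_with_stable_names(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        vec = feat.genomic_features(exon, ctx, genome=genome)
        assert len(vec) == 607
        assert list(vec.index) == feat.genomic_feature_names()

    def test_all_n_exon_zeroes_only_its_kmer_block(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        vec_before = feat.genomic_features(exon, ctx, genome=genome)
        ctx.sequences["A"] = "N" * len(ctx["A"])
        vec = feat.genomic_features(exon, ctx, genome=genome)
        a_kmers = [f for f in vec.index if f.startswith("kmer_A_")]
        assert vec[a_kmers].eq(0).all()
        other = [f for f in vec.index if f.startswith("kmer_") and f not in a_kmers]
        assert np.allclose(vec[other], vec_before[other])

    def test_deterministic(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        v1 = feat.genomic_features(exon, ctx, genome=genome)
        v2 = feat.genomic_features(exon, ctx, genome=genome)
        pd.testing.assert_series_equal(v1, v2)

    def test_conservation_feature_is_masked_mean(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        track = {"chr1": np.full(6000, np.nan)}
        track["chr1"][exon.a[0]:exon.a[0] + 10] = 0.8
        vec = feat.genomic_features(exon, ctx, conservation=track, genome=genome)
        assert vec["cons_A"] == pytest.approx(0.8)
        assert vec["cons_C1"] == 0.0  # entirely missing -> 0


class TestBinarization:
    @pytest.mark.parametrize("p,expected", [
        (0.3, 0.0),    # boundary: <= 0.3 is unmethylated
        (0.0, 0.0),
        (0.7, np.nan),  # boundary excluded: > 0.7 required for methylated
        (0.5, np.nan),
        (0.9, 1.0),
        (1.0, 1.0),
    ])
    def test_thresholds(self, p, expected):
        out = feat.binarize_methylation(p)
        if np.isnan(expected):
            assert np.isnan(out)
        else:
            assert out == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            feat.binarize_methylation(1.2)


class TestMethylationSequence:
    def test_informed_cytosines_use_their_call(self):
        seq, pos = "ACGCA", np.arange(100, 105)
        out = feat.methylation_annotate_sequence(
            seq, pos, "+", np.array([101]), np.array([1.0]))
        assert out[1] == "M"

    def test_uninformed_takes_nearest_within_window(self):
        seq, pos = "ACAAA", np.arange(100, 105)
        out = feat.methylation_annotate_sequence(
            seq, pos, "+", np.array([201]), np.array([0.0]))  # 100 bp away
        assert out[1] == "U"
        out = feat.methylation_annotate_sequence(
            seq, pos, "+", np.array([201]), np.array([1.0]))
        assert out[1] == "M"

    def test_no_information_within_900_defaults_unmethylated(self):
        seq, pos = "ACAAA", np.arange(100, 105)
        out = feat.methylation_annotate_sequence(
            seq, pos, "+", np.array([1101]), np.array([1.0]))  # 1000 bp away
        assert out[1] == "U"

    def test_non_cytosines_unchanged(self):
        seq, pos = "ACGTN", np.arange(5)
        out = feat.methylation_annotate_sequence(
            seq, pos, "+", np.array([1]), np.array([1.0]))
        assert out == "AMGTN"


class TestMethylationFeatures:
    @pytest.fixture(scope="class")
    def setup(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        calls = pd.DataFrame({
            "cell_id": "c0", "chrom": "chr1",
            "pos": np.arange(exon.c1[0], exon.c2[1], 37),
            "value": 1.0,
        })
        return exon, ctx, feat.MethylationIndex(calls)

    def test_width_is_826(self, setup):
        exon, ctx, idx = setup
        block = feat.methylation_features(exon, ctx, idx, cells=["c0"])
        assert block.shape == (1, 826)
        assert list(block.columns) == feat.methylation_feature_names()

    def test_fully_unmethylated_cell_has_no_m_kmers(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        calls = pd.DataFrame({"cell_id": "c0", "chrom": "chr1",
                              "pos": [exon.c1[0]], "value": 0.0})
        block = feat.methylation_features(
            exon, ctx, feat.MethylationIndex(calls), cells=["c0"]).iloc[0]
        m_cols = [c for c in block.index if c.startswith("mkmer_") and
                  "M" in c.rsplit("_", 1)[1]]
        mean_cols = [c for c in block.index if c.startswith("meth_mean_")]
        assert block[m_cols].eq(0).all()
        assert block[mean_cols].eq(0).all()

    def test_mean_mode_of_identical_cells_equals_cell_mode(self, genome):
        exon = make_exon()
        ctx = feat.extract_contexts(exon, genome)
        calls = pd.concat([
            pd.DataFrame({"cell_id": c, "chrom": "chr1",
                          "pos": np.arange(exon.c1[0], exon.c2[1], 53),
                          "value": 1.0})
            for c in ("c0", "c1")
        ])
        idx = feat.MethylationIndex(calls)
        cellwise = feat.methylation_features(exon, ctx, idx, mode="cell")
        meanwise = feat.methylation_features(exon, ctx, idx, mode="mean")
        assert np.allclose(cellwise.iloc[0], cellwise.iloc[1])
        assert np.allclose(meanwise.to_numpy(), cellwise.iloc[0].to_numpy())

    def test_m_to_u_flip_changes_only_mu_columns(self, setup, genome):
        exon, ctx, idx_m = setup
        calls_u = pd.DataFrame({
            "cell_id": "c0", "chrom": "chr1",
            "pos": np.arange(exon.c1[0], exon.c2[1], 37),
            "value": 0.0,
        })
        block_m = feat.methylation_features(exon, ctx, idx_m, cells=["c0"]).iloc[0]
        block_u = feat.methylation_features(
            exon, ctx, feat.MethylationIndex(calls_u), cells=["c0"]).iloc[0]
        # k-mers without M or U do not exist in the block; every column may
        # change except pure-AGT k-mers, which are absent by construction --
        # so verify instead that the genomic block is untouched
        gvec_m = feat.genomic_features(exon, ctx, genome=genome)
        gvec_u = feat.genomic_features(exon, ctx, genome=genome)
        pd.testing.assert_series_equal(gvec_m, gvec_u)
        # and that M-columns and U-columns swapped roles
        m_total = sum(v for c, v in block_m.items()
                      if c.startswith("mkmer_") and "M" in c.rsplit("_", 1)[1])
        u_total = sum(v for c, v in block_u.items()
                      if c.startswith("mkmer_") and "U" in c.rsplit("_", 1)[1])
        assert m_total == pytest.approx(u_total)
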