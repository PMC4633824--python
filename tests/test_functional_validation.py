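import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from eqtel.functional_validation import (
    PWM,
    allelic_imbalance,
    causal_fraction,
    footprint_fraction,
    motif_enrichment,
    read_pwms,
    scan_alleles,
    select_reference_causal,
)

TOY_COUNTS = np.array(
    [[8.0, 1.0, 1.0, 0.0],
     [0.0, 9.0, 0.0, 1.0],
     [1.0, 0.0, 8.0, 1.0],
     [9.0, 0.0, 1.0, 0.0]]
)  # consensus ACGA


def brute_force_pvalues(pwm: PWM, reverse=False):
    """Null survival function by enumerating every background word."""
    m = pwm._matrix(reverse)
    scores = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(m[k, b] for k, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    return scores


class TestPWMPvalues:
    @pytest.mark.parametrize("width", [3, 4, 6, 8])
    def test_dp_equals_enumeration(self, width, rng):
        counts = rng.integers(0, 12, size=(width, 4)).astype(float)
        pwm = PWM.from_counts(counts, "toy")
        exact = brute_force_pvalues(pwm)
        support = sorted(exact)
        for s in [support[0], support[len(support) // 2], support[-1]]:
            brute = sum(p for sc, p in exact.items() if sc >= s)
            assert pwm.match_pvalue(s) == pytest.approx(brute, rel=1e-10)

    def test_nonuniform_background(self, rng):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pwm = PWM.from_counts(TOY_COUNTS, "toy", background=bg)
        exact = brute_force_pvalues(pwm)
        s = sorted(exact)[len(exact) // 3]
        brute = sum(p for sc, p in exact.items() if sc >= s)
        assert pwm.match_pvalue(s) == pytest.approx(brute, rel=1e-10)

    def test_survival_bounds(self):
        pwm = PWM.from_counts(TOY_COUNTS, "toy")
        off, sf, length = pwm.score_distribution()
        assert pwm.match_pvalue(off - 10) == 1.0
        assert pwm.match_pvalue(off + length + 10) == 0.0


class TestScanAlleles:
    def test_identical_alleles_zero_differential(self):
        pwm = PWM.from_counts(TOY_COUNTS, "toy")
        seq = "ATACGATTA"  # 9 bp, SNP centred
        d = scan_alleles(seq, ("G", "G"), pwm)
        assert d.differential == 0.0
        assert d.score_major == d.score_minor

    def test_disruptive_allele_scores_lower(self):
        pwm = PWM.from_counts(TOY_COUNTS, "toy")
        # window where the major allele completes the consensus ACGA
        seq = "TTTACGATTT"[:9]
        d = scan_alleles("TTACGATTT"[:9].ljust(9, "T"), ("G", "T"), pwm)
        # center base participates in the best match for the major allele
        assert d.score_major >= d.score_minor
        assert d.differential == d.score_major - d.score_minor

    def test_hit_threshold_flag(self):
        pwm = PWM.from_counts(TOY_COUNTS, "toy")
        # perfect consensus at the centre: P = (best word mass) ~ (1/4)^4
        seq = "TTACGATTT"[:9]
        d = scan_alleles("TTTACGATT", ("C", "A"), pwm, hit_p=2e-4)
        # toy width-4 motif cannot reach P < 2e-4 (min P = 1/256)
        assert not d.passes_hit_threshold

    def test_ambiguous_bases_skipped(self):
        pwm = PWM.from_counts(TOY_COUNTS, "toy")
        d = scan_alleles("NNNNGNNNN", ("G", "C"), pwm)
        assert d.score_major == d.score_minor == -math.log10(1.0)

    def test_pwm_wider_than_window_rejected(self):
        pwm = PWM.from_counts(np.tile([9.0, 1.0, 1.0, 1.0], (11, 1)), "wide")
        with pytest.raises(ValueError, match="width"):
            scan_alleles("ACGTA", ("G", "C"), pwm)

    def test_even_window_rejected(self):
        pwm = PWM.from_counts(TOY_COUNTS, "toy")
        with pytest.raises(ValueError, match="odd"):
            scan_alleles("ACGTAC", ("G", "C"), pwm)

    def test_reverse_strand_found(self):
        counts = np.array([[20.0, 0, 0, 0]] * 5)  # AAAAA
        pwm = PWM.from_counts(counts, "polyA")
        # TTTTT on the forward strand is AAAAA on the reverse
        d_fwd = scan_alleles("AAAAAAAAA", ("A", "C"), pwm)
        d_rev = scan_alleles("TTTTTTTTT", ("T", "G"), pwm)
        assert d_fwd.score_major == pytest.approx(d_rev.score_major)


def test_read_transfac_pwms(tmp_path):
    text = """\
VV  TEST
XX
//
ID  M0001
BF  none
P0      A      C      G      T
01      8      1      1      0      A
02      0      9      0      1      C
03      1      0      8      1      G
04      9      0      1      0      A
XX
//
"""
    p = tmp_path / "m.transfac"
    p.write_text(text)
    pwms = read_pwms(p, format="transfac")
    assert len(pwms) == 1
    assert pwms[0].width == 4
    np.testing.assert_allclose(pwms[0].probs.sum(axis=1), 1.0)


class TestMotifEnrichment:
    def test_wilcoxon_exact_matches_enumeration(self, rng):
        """6-vs-6 rank-sum: exact P equals full label enumeration."""
        case = np.array([3.1, 2.7, 4.0, 3.5, 2.9, 3.8])
        ctrl = np.array([1.0, 1.4, 0.9, 2.0, 1.1, 1.6])
        df = motif_enrichment({"m": case}, {"m": ctrl}, fold_min=0.0, p_max=1.1)
        p_pkg = df["p_value"].iloc[0]
        # enumeration of all C(12,6) assignments of the pooled values
        pooled = np.r_[case, ctrl]
        obs = sum(
            (c > d) + 0.5 * (c == d) for c in case for d in ctrl
        )
        stats = []
        for idx in itertools.combinations(range(12), 6):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(12) if i not in idx]]
            u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            stats.append(u)
        stats = np.array(stats)
        p_enum = np.mean(np.abs(stats - 18) >= abs(obs - 18) - 1e-12)
        assert p_pkg == pytest.approx(p_enum, rel=1e-9)

    def test_fold_filter_arithmetic(self):
        case = {"m": np.full(10, 2.0)}
        ctrl = {"m": np.full(10, 1.0)}
        df = motif_enrichment(case, ctrl, fold_min=1.5, p_max=1.1)
        assert df["ratio"].iloc[0] == pytest.approx(2.0)

    def test_null_pass_rate_controlled(self, rng):
        passes = 0
        n_rep = 200
        for rep in range(n_rep):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            df = motif_enrichment({"m": x}, {"m": y}, fold_min=0.0, p_max=0.05)
            passes += len(df)
        assert passes / n_rep < 0.10  # type-I error near or below 0.05

    def test_small_case_set_excluded(self):
        df = motif_enrichment({"m": np.ones(3)}, {"m": np.ones(10)})
        assert len(df) == 0

    def test_ordered_by_ratio(self, rng):
        case = {"weak": np.abs(rng.standard_normal(20)) * 1.6,
                "strong": np.abs(rng.standard_normal(20)) * 5.0}
        ctrl = {"weak": np.abs(rng.standard_normal(200)),
                "strong": np.abs(rng.standard_normal(200))}
        df = motif_enrichment(case, ctrl)
        if len(df) == 2:
            assert df["motif_id"].iloc[0] == "strong"


class TestFootprintFraction:
    def test_containment_and_full_coverage(self):
        snps = pd.DataFrame({"chrom": ["1", "1"], "pos": [1000, 5000]})
        iv = pd.DataFrame({"chrom": ["1"], "start": [990], "end": [1010]})
        out = footprint_fraction(snps, iv, flank=25)
        assert out["intervals"] == 0.5
        whole = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [10**7]})
        assert footprint_fraction(snps, whole)["intervals"] == 1.0

    def test_flank_window_logic(self):
        snps = pd.DataFrame({"chrom": ["1"], "pos": [1000]})
        iv = pd.DataFrame({"chrom": ["1"], "start": [1020], "end": [1030]})
        assert footprint_fraction(snps, iv, flank=25)["intervals"] == 1.0
        assert footprint_fraction(snps, iv, flank=10)["intervals"] == 0.0

    def test_split_merge_invariance(self, rng):
        snps = pd.DataFrame({"chrom": ["1"] * 30,
                             "pos": rng.integers(1, 10_000, 30)})
        merged = pd.DataFrame({"chrom": ["1"], "start": [2000], "end": [4000]})
        split = pd.DataFrame({"chrom": ["1"] * 2, "start": [2000, 3001],
                              "end": [3000, 4000]})
        assert footprint_fraction(snps, merged) == footprint_fraction(snps, split)

    def test_random_coverage_expectation(self, rng):
        # intervals tile ~10% of the chromosome; SNP windows of 51 bp
        starts = np.arange(0, 100_000, 1000)
        iv = pd.DataFrame({"chrom": "1", "start": starts + 1,
                           "end": starts + 100})
        snps = pd.DataFrame({"chrom": "1",
                             "pos": rng.integers(500, 99_500, 2000)})
        frac = footprint_fraction(snps, iv, flank=25)["intervals"]
        # window hits iff pos within [start-25, end+25]: coverage 150/1000
        assert frac == pytest.approx(0.15, abs=0.03)

    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError, match="zero SNPs"):
            footprint_fraction(pd.DataFrame(columns=["chrom", "pos"]),
                               pd.DataFrame({"chrom": [], "start": [], "end": []}))


class TestAllelicImbalance:
    def test_balanced_counts(self):
        df = allelic_imbalance(pd.DataFrame(
            {"snp_id": ["a"], "ref_count": [10], "alt_count": [10]}))
        assert df["difference"].iloc[0] == 0
        assert df["abs_log_ratio"].iloc[0] == 0.0

    def test_homozygous_evidence_excluded(self):
        df = allelic_imbalance(pd.DataFrame(
            {"snp_id": ["a", "b"], "ref_count": [20, 0], "alt_count": [0, 0]}))
        assert len(df) == 0

    def test_printed_fold_ratio(self):
        df = allelic_imbalance(pd.DataFrame(
            {"snp_id": ["a"], "ref_count": [657], "alt_count": [100]}))
        assert df["fold"].iloc[0] == pytest.approx(6.57)
        assert df["difference"].iloc[0] == 557


class TestCausalFraction:
    def test_limits(self):
        fr, mean = causal_fraction({"m": 3.0}, {"m": 3.0})
        assert fr["m"] == 1.0
        fr, _ = causal_fraction({"m": 1.0}, {"m": 3.0})
        assert fr["m"] == 0.0

    def test_arithmetic(self):
        fr, mean = causal_fraction({"m": 2.16}, {"m": 3.0})
        assert fr["m"] == pytest.approx((2.16 - 1) / 2.0)
        assert mean == pytest.approx(0.58)

    def test_reference_without_signal_excluded(self):
        fr, mean = causal_fraction({"a": 2.0, "b": 2.0}, {"a": 0.9, "b": 2.0})
        assert list(fr) == ["b"]

    def test_positive_enrichment_required(self):
        with pytest.raises(ValueError, match="> 0"):
            causal_fraction({"m": -1.0}, {"m": 2.0})


def test_select_reference_causal_gap_rule():
    assoc = pd.DataFrame(
        {
            "gene_id": ["g1"] * 3 + ["g2"] * 2,
            "snp_id": ["a", "b", "c", "d", "e"],
            "score": [10.0, 6.0, 1.0, 8.0, 7.0],
        }
    )
    # g1: gap 4 > 2.5 -> 'a' causal; g2: gap 1 -> none
    assert select_reference_causal(assoc, gap_min=2.5) == ["a"]
    assert select_reference_causal(assoc, gap_min=2.5, score_min=11.0) == []


def test_read_meme_minimal_pwms(tmp_path):
    text = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF TOY1
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
 0.800000  0.100000  0.050000  0.050000
 0.050000  0.800000  0.100000  0.050000
 0.050000  0.050000  0.100000  0.800000
"""
    p = tmp_path / "m.meme"
    p.write_text(text)
    pwms = read_pwms(p, format="meme")
    assert len(pwms) == 1 and pwms[0].width == 3
    np.testing.assert_allclose(pwms[0].probs.sum(axis=1), 1.0, atol=1e-6)
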