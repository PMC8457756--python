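"""Word scoring, exact p-values, sequence/region scanning, degenerate words."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dapregulon._seq import revcomp
from dapregulon.genome import (Gene, Genome, MarkovBackground,
                               extract_noncoding_regions, infer_operons)
from dapregulon.motifs import PSSM
from dapregulon.scanning import (BindingSite, ScanThresholds,
                                 calibrate_threshold_null, design_probes,
                                 scan_degenerate_word, scan_regions,
                                 scan_sequence, score_distribution,
                                 score_pvalue, score_word)
from conftest import random_pssm


def enumeration_pvalues(pssm, background, words=None):
    """Independent oracle: exhaust all 4^w words, summing column scores in the
    same left-to-right order as any direct scorer would."""
    lom = np.log2(pssm.frequencies(background)) - background.log2_base[None, :]
    b0 = background.base_freqs
    w = pssm.width
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=w):
        s, p = 0.0, 1.0
        for i, x in enumerate(word):
            s += lom[i, x]
            p *= b0[x]
        scores.append(s)
        probs.append(p)
    scores = np.array(scores)
    probs = np.array(probs)
    order = np.argsort(scores)
    sorted_scores = scores[order]
    survival = np.cumsum(probs[order][::-1])[::-1]

    def pvalue(s):
        idx = np.searchsorted(sorted_scores, s - 1e-9, side="left")
        return survival[min(idx, len(survival) - 1)]

    return scores, pvalue


TWO_WORD = PSSM.from_sites(["ATAGTCC", "ATAGTCT"], pseudocount=0.0)


class TestScoreWord:
    def test_uniform_pssm_scores_zero(self, uniform_bg):
        counts = np.full((6, 4), 5.0)
        p = PSSM(counts, pseudocount=0.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            word = "".join(rng.choice(list("ACGT"), size=6))
            assert score_word(p, word, uniform_bg) == pytest.approx(0.0)

    def test_two_word_matrix_shares_maximal_score(self, uniform_bg):
        s1 = score_word(TWO_WORD, "ATAGTCC", uniform_bg)
        s2 = score_word(TWO_WORD, "ATAGTCT", uniform_bg)
        assert s1 == pytest.approx(s2)
        # six consensus columns at log2(4) plus the split column at log2(2)
        assert s1 == pytest.approx(13.0)
        dist = score_distribution(TWO_WORD, uniform_bg)
        assert s1 == pytest.approx(dist.max_score)

    def test_strand_symmetry_under_order0(self, uniform_bg):
        rng = np.random.default_rng(1)
        p = random_pssm(rng, 8)
        prc = p.reverse_complement()
        for _ in range(10):
            word = "".join(rng.choice(list("ACGT"), size=8))
            assert score_word(p, word, uniform_bg) == pytest.approx(
                score_word(prc, revcomp(word), uniform_bg), abs=1e-9)

    def test_length_mismatch_rejected(self, uniform_bg):
        with pytest.raises(ValueError, match="length"):
            score_word(TWO_WORD, "ACGT", uniform_bg)

    def test_word_with_n_scores_nan(self, uniform_bg):
        assert np.isnan(score_word(TWO_WORD, "ATAGTCN", uniform_bg))


class TestScorePvalue:
    def test_minimum_score_has_full_mass(self, uniform_bg):
        rng = np.random.default_rng(2)
        p = random_pssm(rng, 6)
        dist = score_distribution(p, uniform_bg)
        assert dist.pvalue(dist.min_score) == pytest.approx(1.0)

    def test_two_word_top_pvalue_reproduces_threshold_override(self, uniform_bg):
        # exactly two of the 4^7 words attain the top score
        p_top = score_pvalue(TWO_WORD, uniform_bg, 13.0)
        assert p_top == pytest.approx(2 * 4 ** -7)
        assert 1e-4 < p_top <= 2e-4

    def test_dp_matches_enumeration(self, uniform_bg):
        rng = np.random.default_rng(3)
        for width in (4, 5, 6):
            p = random_pssm(rng, width)
            b0 = np.array([0.3, 0.2, 0.2, 0.3])
            bg = MarkovBackground(0, b0[None, :], b0)
            dist = score_distribution(p, bg)
            scores, oracle = enumeration_pvalues(p, bg)
            query = rng.choice(scores, size=200)
            for s in query:
                assert dist.pvalue(s) == pytest.approx(oracle(s), abs=1e-9)

    def test_monotone_in_score(self, uniform_bg):
        rng = np.random.default_rng(4)
        p = random_pssm(rng, 7)
        dist = score_distribution(p, uniform_bg)
        ss = np.sort(rng.uniform(dist.min_score, dist.max_score, size=100))
        ps = [dist.pvalue(s) for s in ss]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_wide_matrix_grid_path_consistent(self, uniform_bg):
        # the epsilon-grid DP (w > exact cutoff) matches the exact DP where
        # both are available
        rng = np.random.default_rng(5)
        p = random_pssm(rng, 8)
        exact = score_distribution(p, uniform_bg, max_exact_width=9)
        grid = score_distribution(p, uniform_bg, max_exact_width=0)
        for s in rng.uniform(exact.min_score, exact.max_score, size=50):
            assert grid.pvalue(s) == pytest.approx(exact.pvalue(s), rel=1e-3,
                                                   abs=1e-12)


class TestScanSequence:
    def test_planted_consensus_found_at_offset(self, uniform_bg):
        rng = np.random.default_rng(6)
        word = "TTGACAGGCATTGC"
        p = PSSM.from_sites([word] * 10)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        seq = seq[:100] + word + seq[100 + len(word):]
        sites = scan_sequence(p, seq, uniform_bg, threshold_p=1e-4)
        assert any(s.location == 100 and s.strand == "+" for s in sites)
        best = min(sites, key=lambda s: s.p_value)
        assert best.location == 100
        assert best.matched_word == word

    def test_threshold_one_reports_every_position(self, uniform_bg):
        rng = np.random.default_rng(7)
        p = random_pssm(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), size=50))
        sites = scan_sequence(p, seq, uniform_bg, threshold_p=1.0)
        assert len(sites) == 2 * (50 - 5 + 1)

    def test_strand_covariance(self, uniform_bg):
        rng = np.random.default_rng(8)
        p = random_pssm(rng, 8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fwd = scan_sequence(p, seq, uniform_bg, threshold_p=1e-3)
        rev = scan_sequence(p, revcomp(seq), uniform_bg, threshold_p=1e-3)
        L = len(seq)
        mirrored = {(L - s.location - s.width, {"+": "-", "-": "+"}[s.strand])
                    for s in rev}
        assert {(s.location, s.strand) for s in fwd} == mirrored

    def test_windows_with_n_skipped(self, uniform_bg):
        p = PSSM.from_sites(["ACGTACGT"] * 4)
        seq = "ACGTNCGTACGTACGT"
        sites = scan_sequence(p, seq, uniform_bg, threshold_p=1.0)
        assert all(not ("N" in seq[s.location:s.location + 8]) for s in sites)


def two_region_fixture(word_a="ATAGTCC", word_b="ATAGTCT"):
    """A genome with two operon heads whose windows hold the two BlaI-style words."""
    rng = np.random.default_rng(9)
    seq = list("".join(rng.choice(list("ACGT"), size=4000)))
    genes = [Gene("up1", 200, 500, "+"), Gene("head1", 1000, 1900, "+"),
             Gene("up2", 2100, 2400, "+"), Gene("head2", 2900, 3800, "+")]
    seq[800:807] = list(word_a)
    seq[2700:2707] = list(word_b)
    genome = Genome(id="two", sequence="".join(seq))
    operons = infer_operons(genes, max_gap=100)
    regions = extract_noncoding_regions(genome, operons)
    return genome, operons, regions


class TestScanRegions:
    def test_override_threshold_admits_both_words(self, uniform_bg):
        genome, operons, regions = two_region_fixture()
        ths = ScanThresholds(overrides={"BlaI_1845": 2e-4})
        sites = scan_regions(TWO_WORD, regions, genome, uniform_bg, ths,
                             tf="BlaI_1845")
        words = {s.matched_word for s in sites if s.strand == "+"}
        assert {"ATAGTCC", "ATAGTCT"} <= words

    def test_default_threshold_rejects_top_score(self, uniform_bg):
        genome, operons, regions = two_region_fixture()
        ths = ScanThresholds()  # p_genome = 1e-5 < the words' exact p
        sites = scan_regions(TWO_WORD, regions, genome, uniform_bg, ths)
        assert sites == []

    def test_unknown_override_key_warns_and_uses_default(self, uniform_bg, caplog):
        genome, operons, regions = two_region_fixture()
        ths = ScanThresholds(overrides={"OtherTF": 2e-4})
        with caplog.at_level("WARNING"):
            scan_regions(TWO_WORD, regions, genome, uniform_bg, ths, tf="BlaI_1845")
        assert any("override" in r.message for r in caplog.records)

    def test_empty_region_list(self, uniform_bg):
        genome, _, _ = two_region_fixture()
        assert scan_regions(TWO_WORD, [], genome, uniform_bg,
                            ScanThresholds()) == []

    def test_divergent_shared_site_reported_once_with_both_operons(self, uniform_bg):
        rng = np.random.default_rng(10)
        word = "TTGACAGGCATTGC"
        seq = list("".join(rng.choice(list("ACGT"), size=2500)))
        seq[600:614] = list(word)  # inside the shared stretch
        genome = Genome(id="d", sequence="".join(seq))
        genes = [Gene("left", 0, 500, "-"), Gene("right", 700, 1500, "+")]
        operons = infer_operons(genes)
        regions = extract_noncoding_regions(genome, operons)
        p = PSSM.from_sites([word] * 10)
        sites = scan_regions(p, regions, genome, uniform_bg,
                             ScanThresholds(p_genome=1e-4))
        exact = [s for s in sites if s.location == 600 and s.strand == "+"]
        assert len(exact) == 1
        assert set(exact[0].operons) == {"left", "right"}


class TestDegenerateWords:
    def test_exact_instance_of_gapped_pattern(self):
        seq = "CCCCGTAATATTACCCCC"
        sites = scan_degenerate_word("GTAANNTTAC", seq, max_mismatch=0)
        assert len(sites) == 1
        assert sites[0].location == 4
        assert sites[0].matched_word == "GTAATATTAC"

    def test_self_reverse_complementary_pattern_reported_once(self):
        assert revcomp("GTAANNTTAC") == "GTAANNTTAC"
        seq = "AAAGTAATATTACAAA"
        sites = scan_degenerate_word("GTAANNTTAC", seq, max_mismatch=0)
        assert len(sites) == 1  # one duplex occurrence, not one per strand

    def test_both_strands_counted_for_asymmetric_word(self):
        # GTAA reads once forward and once (as TTAC) on the reverse strand
        sites = scan_degenerate_word("GTAA", "GTAATATTAC", max_mismatch=0)
        assert len(sites) == 2
        assert {s.strand for s in sites} == {"+", "-"}

    def test_arm_mismatch_not_tolerated_at_zero(self):
        pattern = "TACATCNNNNNNGATGTA"
        hit = "TACATCAAAAAAGATGTA"
        miss = "TACGTCAAAAAAGATGTA"  # one arm mismatch
        assert len(scan_degenerate_word(pattern, "CC" + hit + "CC", 0)) == 1
        assert scan_degenerate_word(pattern, "CC" + miss + "CC", 0) == []
        assert len(scan_degenerate_word(pattern, "CC" + miss + "CC", 1)) == 1

    def test_excessive_mismatch_budget_rejected(self):
        with pytest.raises(ValueError, match="max_mismatch"):
            scan_degenerate_word("GTNN", "ACGTACGT", max_mismatch=2)


class TestCalibration:
    def test_planted_signal_exceeds_null_quantile(self, uniform_bg):
        rng = np.random.default_rng(11)
        word = "TTGACAGGCATTGC"
        p = PSSM.from_sites([word] * 10)
        seq = list("".join(rng.choice(list("ACGT"), size=6000)))
        genes = []
        for i in range(4):
            base = 1000 + i * 1200
            seq[base - 300:base - 300 + len(word)] = list(word)
            genes.append(Gene(f"g{i}", base, base + 600, "+"))
        genome = Genome(id="c", sequence="".join(seq))
        regions = extract_noncoding_regions(genome, infer_operons(genes, 100))
        observed = sum(len(scan_regions(p, regions, genome, uniform_bg,
                                        ScanThresholds(p_genome=1e-4))) for _ in [0])
        null = calibrate_threshold_null(p, regions, genome, uniform_bg,
                                        n_shuffles=10, seed=0,
                                        thresholds=(1e-4,))
        assert observed > null[1e-4]["q95"]

    def test_zero_shuffles_rejected(self, uniform_bg):
        with pytest.raises(ValueError, match="n_shuffles"):
            calibrate_threshold_null(TWO_WORD, [], None, uniform_bg, n_shuffles=0)


class TestDesignProbes:
    def make_peak_seqs(self, uniform_bg):
        rng = np.random.default_rng(12)
        word = "TTGACAGGCATTGC"
        p = PSSM.from_sites([word] * 10)
        seqs = []
        from dapregulon.peaks import PeakSequence

        for i in range(3):
            s = "".join(rng.choice(list("ACGT"), size=200))
            if i == 0:
                s = s[:80] + word + s[80 + len(word):]
            seqs.append(PeakSequence(peak_id=f"p{i}", sequence=s, start=0,
                                     apex_offset=100, fold_change=10.0 - i))
        return p, seqs

    def test_probe_lengths_follow_flank_rule(self, uniform_bg):
        p, seqs = self.make_peak_seqs(uniform_bg)
        pos, neg = design_probes(p, seqs, uniform_bg, flank=10)
        assert len(pos) == 14 + 20
        assert len(neg) == len(pos)
        assert "TTGACAGGCATTGC" in pos

    def test_negative_probe_has_no_match(self, uniform_bg):
        p, seqs = self.make_peak_seqs(uniform_bg)
        _, neg = design_probes(p, seqs, uniform_bg, flank=10)
        hits = scan_sequence(p, neg, uniform_bg, threshold_p=1e-3)
        assert hits == []

    def test_zero_flank_equals_site_word(self, uniform_bg):
        p, seqs = self.make_peak_seqs(uniform_bg)
        pos, _ = design_probes(p, seqs, uniform_bg, flank=0)
        assert pos == "TTGACAGGCATTGC"

    def test_no_site_is_an_error(self, uniform_bg):
        rng = np.random.default_rng(13)
        p = PSSM.from_sites(["TTGACAGGCATTGC"] * 10)
        from dapregulon.peaks import PeakSequence

        seqs = [PeakSequence("p", "".join(rng.choice(list("ACGT"), 100)), 0, 50)]
        with pytest.raises(ValueError, match="no binding site"):
            design_probes(p, seqs, uniform_bg)


class TestThresholdConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScanThresholds(p_peak=0.0)
        with pytest.raises(ValueError):
            ScanThresholds(overrides={"x": 2.0})

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "thresholds.yaml"
        path.write_text("p_peak: 1.0e-4\np_genome: 1.0e-5\n"
                        "overrides:\n  BlaI_1845: 2.0e-4\n")
        ths = ScanThresholds.from_yaml(path)
        assert ths.genome_threshold("BlaI_1845") == pytest.approx(2e-4)
        assert ths.genome_threshold(None) == pytest.approx(1e-5)
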