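"""PWM scanning against a first-order Markov background."""

import numpy as np
import pytest

from corebind.genome import Interval
from corebind.motif import (
    MarkovBackground,
    PWMCounts,
    PWMModel,
    build_pwm,
    consensus,
    fit_markov1,
    interval_match_fraction,
    read_pwm_counts,
    reverse_complement,
    scan_sequences,
    score_word,
)
from corebind.simulate import default_pwm_counts


def uniform_bg():
    return MarkovBackground(pi=np.full(4, 0.25), trans=np.full((4, 4), 0.25))


class TestMarkovFit:
    def test_transition_counts_by_hand(self):
        bg = fit_markov1(["AAAC"], pseudocount=0)
        assert bg.trans[0, 0] == pytest.approx(2 / 3)  # AA twice of three A-steps
        assert bg.trans[0, 1] == pytest.approx(1 / 3)  # AC once
        assert bg.pi[0] == pytest.approx(3 / 4)
        assert bg.pi[1] == pytest.approx(1 / 4)

    def test_uniform_sequence_yields_uniform_transitions(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200_000))
        bg = fit_markov1([seq])
        assert np.allclose(bg.trans, 0.25, atol=0.01)
        assert np.allclose(bg.pi, 0.25, atol=0.01)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_markov1([])

    def test_ambiguous_bases_break_chains(self):
        # "AANAA" has transitions AA, AA only (N breaks the chain)
        bg = fit_markov1(["AANAA"], pseudocount=0)
        assert bg.trans[0, 0] == pytest.approx(1.0)


class TestBuildPwm:
    def test_pseudocount_smoothing_by_hand(self):
        pwm = build_pwm(PWMCounts(np.array([[2.0], [0.0], [0.0], [0.0]])), 0.25)
        assert pwm.probs[0, 0] == pytest.approx(2.25 / 3)

    def test_flat_column_stays_flat(self):
        pwm = build_pwm(PWMCounts(np.ones((4, 3))), 0.5)
        assert np.allclose(pwm.probs, 0.25)

    def test_zero_column_with_zero_pseudocount_errors(self):
        with pytest.raises(ValueError):
            PWMCounts(np.zeros((4, 2)))


class TestScoreWord:
    def test_width_one_ratio(self):
        pwm = PWMModel(np.array([[0.8], [0.1], [0.05], [0.05]]))
        w = score_word("A", pwm, uniform_bg())
        assert w == pytest.approx(np.log2(0.8 / 0.25))

    def test_zero_weight_when_probabilities_match(self):
        pwm = PWMModel(np.full((4, 2), 0.25))
        assert score_word("AC", pwm, uniform_bg()) == pytest.approx(0.0)

    def test_ambiguous_base_skipped(self):
        pwm = PWMModel(np.full((4, 2), 0.25))
        assert score_word("AN", pwm, uniform_bg()) is None

    def test_matches_log_free_brute_force(self, rng):
        # explicit probability products, no logs, widths up to 8
        for width in range(1, 9):
            counts = rng.integers(0, 50, size=(4, width)).astype(float) + 1
            pwm = build_pwm(PWMCounts(counts))
            pi = rng.dirichlet(np.ones(4))
            trans = rng.dirichlet(np.ones(4), size=4)
            bg = MarkovBackground(pi=pi, trans=trans)
            for _ in range(20):
                word = "".join("ACGT"[i] for i in rng.integers(0, 4, width))
                idx = ["ACGT".index(c) for c in word]
                p_fg = 1.0
                for j, b in enumerate(idx):
                    p_fg *= pwm.probs[b, j]
                p_bg = pi[idx[0]]
                for a, b in zip(idx, idx[1:]):
                    p_bg *= trans[a, b]
                expected = np.log2(p_fg) - np.log2(p_bg)
                assert score_word(word, pwm, bg) == pytest.approx(expected, abs=1e-9)

    def test_background_words_have_nonpositive_expected_weight(self, rng):
        # Gibbs inequality: E_bg[weight] <= 0 for any PWM
        pwm = build_pwm(PWMCounts(rng.integers(1, 60, (4, 6)).astype(float)))
        bg = uniform_bg()
        words = ["".join("ACGT"[i] for i in rng.integers(0, 4, 6))
                 for _ in range(10_000)]
        weights = [score_word(w, pwm, bg) for w in words]
        assert np.mean(weights) <= 0.0


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng):
        pwm = build_pwm(default_pwm_counts())
        cons = consensus(pwm)
        bgseq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        seq = bgseq[:37] + cons + bgseq[37 + len(cons):]
        bg = uniform_bg()
        hits = scan_sequences({"s": seq}, pwm, bg, threshold=4.0)
        offs = {h.offset for h in hits if h.strand == "+"}
        assert 37 in offs
        best = max(h.weight for h in hits)
        assert any(h.offset == 37 for h in hits if h.weight == best)

    def test_threshold_above_max_gives_no_hits(self, rng):
        pwm = build_pwm(default_pwm_counts())
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        assert scan_sequences({"s": seq}, pwm, uniform_bg(), threshold=1e6) == []

    def test_palindromic_site_hits_both_strands(self):
        site = "ACGCGT"  # reverse complement of itself
        counts = np.full((4, 6), 0.0)
        for j, b in enumerate(site):
            counts["ACGT".index(b), j] = 100.0
        pwm = build_pwm(PWMCounts(counts))
        seq = "TTTTTT" + site + "TTTTTT"
        hits = scan_sequences({"s": seq}, pwm, uniform_bg(), threshold=4.0)
        strands = {h.strand for h in hits if h.offset == 6}
        assert strands == {"+", "-"}

    def test_strand_symmetry_of_scanning(self, rng):
        pwm = build_pwm(PWMCounts(rng.integers(1, 60, (4, 6)).astype(float)))
        bg = uniform_bg()
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        hits_fwd = scan_sequences({"s": seq}, pwm, bg, threshold=2.0)
        hits_rc = scan_sequences({"s": reverse_complement(seq)}, pwm, bg, threshold=2.0)
        L, W = len(seq), pwm.width
        mirrored = sorted(
            (L - W - h.offset, "-" if h.strand == "+" else "+", round(h.weight, 9))
            for h in hits_rc
        )
        original = sorted((h.offset, h.strand, round(h.weight, 9)) for h in hits_fwd)
        assert original == mirrored


class TestIntervalMatchFraction:
    def test_motif_in_every_interval(self, rng):
        pwm = build_pwm(default_pwm_counts())
        cons = consensus(pwm)
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        chrom = chrom[:100] + cons + chrom[100 + len(cons):]
        chrom = chrom[:1000] + cons + chrom[1000 + len(cons):]
        ivs = [Interval("c", 50, 200), Interval("c", 950, 1100)]
        frac = interval_match_fraction(ivs, {"c": chrom}, pwm, uniform_bg(), 4.0)
        assert frac == 1.0

    def test_infinite_threshold_gives_zero(self, rng):
        pwm = build_pwm(default_pwm_counts())
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        ivs = [Interval("c", 0, 400), Interval("c", 500, 900)]
        assert interval_match_fraction(ivs, {"c": chrom}, pwm, uniform_bg(), np.inf) == 0.0

    def test_out_of_bounds_interval_errors(self):
        pwm = build_pwm(default_pwm_counts())
        with pytest.raises(ValueError):
            interval_match_fraction(
                [Interval("c", 0, 50)], {"c": "ACGT"}, pwm, uniform_bg(), 4.0
            )


class TestPwmIO:
    def test_read_counts_with_row_labels(self, tmp_path):
        p = tmp_path / "pwm.txt"
        p.write_text("A: 10 2\nC: 1 3\nG: 0 90\nT: 5 5\n")
        counts = read_pwm_counts(p)
        assert counts.counts[0, 0] == 10 and counts.counts[2, 1] == 90

    def test_wrong_row_count_errors(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 2\n3 4\n")
        with pytest.raises(ValueError):
            read_pwm_counts(p)
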