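import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistf.diff_classify import RegulatedSets
from cistf.io_formats import GeneModel, GenomeSequences, Peak, PWMMotif
from cistf.motif_enrichment import (
    BACKGROUND_LABELS,
    BackgroundSuite,
    ame_optimal_enrichment,
    build_background_suite,
    dinuc_shuffle,
    fisher_upper_tail,
    genome_base_frequencies,
    log_fisher_upper_tail,
    pwm_to_log_odds,
    run_enrichment_suite,
    score_sequence,
    score_sequences,
)
from cistf.synthetic_data import consensus_pwm, revcomp


def exact_fisher_upper_tail(k, n, K_bg, n_bg):
    """Exact rational hypergeometric upper tail, independent enumeration."""
    N, K, draws = n + n_bg, k + K_bg, n
    total = Fraction(0)
    for i in range(k, min(draws, K) + 1):
        if draws - i <= N - K:
            total += Fraction(math.comb(K, i) * math.comb(N - K, draws - i),
                              math.comb(N, draws))
    return total


def dinuc_counts(seq):
    out = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


class TestPwmToLogOdds:
    def test_uniform_row_scores_zero(self):
        m = PWMMotif("m", [[0.25] * 4, [0.25] * 4])
        lom = pwm_to_log_odds(m)
        np.testing.assert_allclose(lom.matrix, 0.0, atol=1e-12)

    def test_certain_base_approaches_log2_4(self):
        m = PWMMotif("m", [[1.0, 0.0, 0.0, 0.0]])
        lom = pwm_to_log_odds(m, pseudocount=1e-9)
        assert lom.matrix[0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_expected_log_odds_under_background_nonpositive(self, rng):
        # direct summation: E_bg[log odds] = -KL(bg || smoothed row) <= 0
        for _ in range(20):
            mat = rng.dirichlet([1.0] * 4, size=5)
            bg = rng.dirichlet([5.0] * 4)
            lom = pwm_to_log_odds(PWMMotif("m", mat), background=bg)
            expected = (lom.matrix * bg[None, :]).sum(axis=1)
            assert np.all(expected <= 1e-9)

    def test_zero_background_raises(self):
        with pytest.raises(ValueError):
            pwm_to_log_odds(PWMMotif("m", [[0.25] * 4]), background=[0.5, 0.5, 0.0, 0.0])


def brute_force_score(seq, lom):
    """Exhaustive double-strand window scan in plain python."""
    L = lom.length
    best = float("-inf")
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - L + 1):
            win = s[i:i + L]
            if "N" in win:
                continue
            val = sum(lom.matrix[j, "ACGT".index(b)] for j, b in enumerate(win))
            best = max(best, val)
    return best


class TestScoreSequence:
    MOTIF = PWMMotif("m", consensus_pwm("TGACTCA"))

    def test_consensus_sequence_scores_max_sum(self):
        lom = pwm_to_log_odds(self.MOTIF)
        score = score_sequence("TGACTCA", lom).score
        assert score == pytest.approx(lom.matrix.max(axis=1).sum())

    def test_palindromic_motif_strand_symmetric(self, rng):
        pal = PWMMotif("pal", consensus_pwm("TGCA"))
        lom = pwm_to_log_odds(pal)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            assert score_sequence(seq, lom).score == pytest.approx(
                score_sequence(revcomp(seq), lom).score)

    def test_matches_brute_force_on_random_60mers(self):
        rng = np.random.default_rng(11)
        lom = pwm_to_log_odds(self.MOTIF, background=[0.3, 0.2, 0.2, 0.3])
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=60, p=[0.24] * 4 + [0.04]))
            got = score_sequence(seq, lom).score
            assert got == pytest.approx(brute_force_score(seq, lom))

    def test_reported_position_and_strand_locate_the_site(self):
        lom = pwm_to_log_odds(self.MOTIF)
        sc = score_sequence("AAAAA" + "TGACTCA" + "AAAA", lom)
        assert (sc.position, sc.strand) == (5, "+")
        sc_rc = score_sequence("AAAAA" + revcomp("TGACTCA") + "AAAA", lom)
        assert (sc_rc.position, sc_rc.strand) == (5, "-")

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            score_sequence("", pwm_to_log_odds(self.MOTIF))

    def test_all_n_sequence_excluded(self):
        lom = pwm_to_log_odds(self.MOTIF)
        assert score_sequence("N" * 30, lom).score == float("-inf")

    def test_avg_scoring_bounded_by_max(self, rng):
        lom = pwm_to_log_odds(self.MOTIF)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert score_sequence(seq, lom, scoring="avg").score <= \
                score_sequence(seq, lom, scoring="max").score + 1e-9


class TestFisherUpperTail:
    def test_zero_hits_gives_one(self):
        assert fisher_upper_tail(0, 5, 3, 7) == 1.0

    def test_derived_small_table(self):
        # 3/5 fg hits vs 1/5 bg hits: exact enumeration gives 11/42
        exact = exact_fisher_upper_tail(3, 5, 1, 5)
        assert exact == Fraction(11, 42)
        assert fisher_upper_tail(3, 5, 1, 5) == pytest.approx(float(exact), rel=1e-12)

    def test_closed_form_extreme_table(self):
        assert fisher_upper_tail(5, 5, 0, 1000) == pytest.approx(
            1.0 / math.comb(1005, 5), rel=1e-9)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            fisher_upper_tail(-1, 5, 0, 5)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 8), st.integers(1, 10), st.integers(0, 8), st.integers(1, 10))
    def test_monotone_in_foreground_hits(self, k, n, kb, nb):
        k = min(k, n - 1)
        kb = min(kb, nb)
        p1 = log_fisher_upper_tail(k, n, kb, nb)
        p2 = log_fisher_upper_tail(k + 1, n, kb, nb)
        assert p2 <= p1 + 1e-12

    def test_deep_tail_stays_finite_in_log_space(self):
        lp = log_fisher_upper_tail(2000, 2000, 0, 2000)
        assert math.isfinite(lp) and lp < -2000


def brute_force_optimal(fg, bg):
    """Scan every distinct observed score (fg and bg) as a threshold."""
    best = 0.0
    for t in sorted(set(fg) | set(bg)):
        k = sum(1 for v in fg if v >= t)
        b = sum(1 for v in bg if v >= t)
        best = min(best, log_fisher_upper_tail(k, len(fg), b, len(bg)))
    return best


class TestOptimalEnrichment:
    def test_perfect_separation(self):
        opt = ame_optimal_enrichment([10.0] * 8, [0.0] * 8)
        assert opt.threshold_star == 10.0
        assert opt.log_p_raw == pytest.approx(log_fisher_upper_tail(8, 8, 0, 8))

    def test_identical_distributions_null(self, rng):
        scores = rng.normal(size=50)
        opt = ame_optimal_enrichment(scores, scores)
        assert opt.log_p_adj_thresholds > math.log(0.2)

    def test_foreground_thresholds_lose_nothing(self):
        # property: restricting candidates to fg scores attains the global min
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fg = rng.integers(0, 10, size=rng.integers(5, 30)).astype(float)
            bg = rng.integers(0, 10, size=rng.integers(5, 30)).astype(float)
            opt = ame_optimal_enrichment(fg, bg)
            assert opt.log_p_raw == pytest.approx(brute_force_optimal(fg, bg), abs=1e-10)

    def test_all_non_finite_raises(self):
        with pytest.raises(ValueError):
            ame_optimal_enrichment([float("-inf")], [1.0])

    def test_threshold_bonferroni_at_least_raw(self, rng):
        fg, bg = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        opt = ame_optimal_enrichment(fg, bg)
        assert opt.log_p_adj_thresholds >= opt.log_p_raw


class TestDinucShuffle:
    def test_monotone_sequence_fixed_point(self, rng):
        assert dinuc_shuffle("AAAA", rng) == "AAAA"

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=2, max_size=80),
           st.integers(0, 2**31 - 1))
    def test_counts_and_endpoints_preserved(self, seq, seed):
        out = dinuc_shuffle(seq, np.random.default_rng(seed))
        assert dinuc_counts(out) == dinuc_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_some_seed_rearranges(self):
        # needs a sequence whose dinucleotide graph admits several Eulerian paths
        # (a pure ACGT repeat is a cycle with a single arrangement)
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=60))
        outs = {dinuc_shuffle(seq, np.random.default_rng(s)) for s in range(20)}
        assert any(o != seq for o in outs)
        assert all(dinuc_counts(o) == dinuc_counts(seq) for o in outs)


def _toy_world():
    """Hand-enumerable fixture: one significant gene, one neutral gene, labeled peaks."""
    genome = GenomeSequences({"chr1": "ACGT" * 300_000})  # 1.2 Mb
    sig_gene = GeneModel("gsig", "chr1", "+", 100_000)
    neu_gene = GeneModel("gneu", "chr1", "+", 700_000)
    genes = [sig_gene, neu_gene]
    peaks = [
        Peak("chr1", 100_500, 100_700, "conc"),        # concordant fasted_opened
        Peak("chr1", 1_150_000, 1_150_200, "nonconc"),  # fasted_opened, far from gsig
        Peak("chr1", 101_000, 101_200, "neu_near_sig"),
        Peak("chr1", 700_500, 700_700, "neu_near_neu"),
        Peak("chr1", 1_100_000, 1_100_200, "neu_far"),
    ]
    reg = RegulatedSets(fasted_opened={"conc", "nonconc"}, fasting_induced={"gsig"})
    return genome, genes, peaks, reg


class TestBackgroundSuite:
    def test_membership_matches_hand_truth_table(self):
        genome, genes, peaks, reg = _toy_world()
        from cistf.concordance import assign_concordant_peaks
        conc = assign_concordant_peaks(peaks, genes, reg)["fasted_opened"]
        suite = build_background_suite("fasted_opened", conc, peaks, reg, genes,
                                       genome, rng_seed=1)
        ids = suite.peak_ids
        assert set(ids["neutral_all"]) == {"neu_near_sig", "neu_near_neu", "neu_far"}
        assert set(ids["neutral_near_neutral_genes"]) == {"neu_near_neu"}
        assert set(ids["neutral_near_significant_genes"]) == {"neu_near_sig"}
        assert set(ids["neutral_near_tss"]) == {"neu_near_sig", "neu_near_neu"}
        assert set(ids["non_concordant"]) == {"nonconc"}

    def test_shuffled_set_matches_foreground_cardinality_and_lengths(self):
        genome, genes, peaks, reg = _toy_world()
        from cistf.concordance import assign_concordant_peaks
        conc = assign_concordant_peaks(peaks, genes, reg)["fasted_opened"]
        suite = build_background_suite("fasted_opened", conc, peaks, reg, genes,
                                       genome, rng_seed=1)
        shuf = suite.sets["shuffled_foreground"]
        assert len(shuf) == len(conc.peak_ids)
        assert sorted(len(s) for s in shuf.values()) == [200]

    def test_non_concordant_disjoint_from_foreground(self):
        genome, genes, peaks, reg = _toy_world()
        from cistf.concordance import assign_concordant_peaks
        conc = assign_concordant_peaks(peaks, genes, reg)["fasted_opened"]
        suite = build_background_suite("fasted_opened", conc, peaks, reg, genes,
                                       genome, rng_seed=1)
        assert set(suite.peak_ids["non_concordant"]) & set(conc.peak_ids) == set()

    def test_empty_set_error_names_the_set(self):
        genome, genes, peaks, reg = _toy_world()
        from cistf.concordance import assign_concordant_peaks
        peaks = [p for p in peaks if p.peak_id != "neu_near_neu"]
        conc = assign_concordant_peaks(peaks, genes, reg)["fasted_opened"]
        with pytest.raises(ValueError, match="neutral_near_neutral_genes"):
            build_background_suite("fasted_opened", conc, peaks, reg, genes,
                                   genome, rng_seed=1)


def _planted_suite(rng, motif, n=50, length=120, p_fg=0.8, p_bg=0.05):
    def rand_seq():
        return "".join(rng.choice(list("ACGT"), size=length))

    def plant(seq, prob):
        if rng.random() >= prob:
            return seq
        inst = "".join("ACGT"[int(np.argmax(row))] for row in motif.matrix)
        off = int(rng.integers(0, length - len(inst)))
        return seq[:off] + inst + seq[off + len(inst):]

    fg = {f"fg{i}": plant(rand_seq(), p_fg) for i in range(n)}
    sets = {}
    for label in BACKGROUND_LABELS[:-1]:
        sets[label] = {f"{label}{i}": plant(rand_seq(), p_bg) for i in range(n)}
    shuffle_rng = np.random.default_rng(5)
    sets["shuffled_foreground"] = {f"{k}_shuf": dinuc_shuffle(s, shuffle_rng)
                                   for k, s in fg.items()}
    return fg, BackgroundSuite(condition="fasted_opened", sets=sets, seed=5)


class TestRunEnrichmentSuite:
    MOTIF = PWMMotif("planted", consensus_pwm("TGACGTCATCGA"))
    DECOY = PWMMotif("decoy", consensus_pwm("TGACGTCATCGA")[::-1])

    def test_single_motif_bonferroni_factor_is_one(self):
        rng = np.random.default_rng(1)
        fg, suite = _planted_suite(rng, self.MOTIF)
        res = run_enrichment_suite(fg, suite, [self.MOTIF])
        for r in res["planted"].values():
            # with a single motif the library Bonferroni factor is 1
            assert r.log_p_adj == pytest.approx(
                min(0.0, r.log_p_raw + math.log(r.n_thresholds)), abs=1e-12)

    def test_planted_motif_significant_in_all_six_backgrounds(self):
        rng = np.random.default_rng(1)
        fg, suite = _planted_suite(rng, self.MOTIF)
        res = run_enrichment_suite(fg, suite, [self.MOTIF, self.DECOY])
        planted = res["planted"]
        assert len(planted) == 6
        assert all(r.log_p_adj < math.log(0.05) for r in planted.values())

    def test_decoy_motif_not_significant(self):
        rng = np.random.default_rng(1)
        fg, suite = _planted_suite(rng, self.MOTIF)
        res = run_enrichment_suite(fg, suite, [self.MOTIF, self.DECOY])
        assert all(r.log_p_adj > math.log(0.05) for r in res["decoy"].values())

    def test_doubling_library_doubles_adjusted_p(self):
        rng = np.random.default_rng(2)
        fg, suite = _planted_suite(rng, self.MOTIF)
        r1 = run_enrichment_suite(fg, suite, [self.MOTIF])["planted"]
        extra = PWMMotif("pad", consensus_pwm("ACACACAGTGTG"))
        r2 = run_enrichment_suite(fg, suite, [self.MOTIF, extra])["planted"]
        for label in BACKGROUND_LABELS:
            uncapped = r1[label].log_p_adj < -math.log(2.0)
            if uncapped:
                assert r2[label].log_p_adj == pytest.approx(
                    r1[label].log_p_adj + math.log(2.0), abs=1e-12)
            else:
                assert r2[label].log_p_adj <= 0.0


class TestGenomeBaseFrequencies:
    def test_counts_ignore_n(self):
        g = GenomeSequences({"c": "AACCGGTTNN"})
        np.testing.assert_allclose(genome_base_frequencies(g), [0.25] * 4)
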