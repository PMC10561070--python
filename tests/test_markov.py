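import numpy as np
import pytest
from scipy import stats

from irscape.counting import pair_count_spectrum
from irscape.genome_io import MaskedChromosome, Window, encode_sequence
from irscape.markov import (
    MarkovModel,
    fit_markov,
    pair_probability,
    rc_permutation,
    simulate_sequence,
    string_to_word,
    word_to_string,
)
from irscape.synthetic import preset_model


def _chrom(seq, name="c"):
    return MaskedChromosome(name, encode_sequence(seq))


class TestFit:
    def test_hand_counts_on_aacc(self):
        m = fit_markov(_chrom("AACC"), 1)
        np.testing.assert_allclose(m.pi, [0.5, 0.5, 0, 0])
        np.testing.assert_allclose(m.trans[0], [0.5, 0.5, 0, 0])  # AA, AC
        np.testing.assert_allclose(m.trans[1], [0, 1, 0, 0])      # CC

    def test_degenerate_chain(self):
        m = fit_markov(_chrom("AAAA"), 1)
        assert m.pi[0] == 1 and m.trans[0, 0] == 1

    def test_adjacencies_never_cross_separators(self):
        m = fit_markov(_chrom("ACNGT"), 1)
        # only A->C and G->T observed; C and T rows fall back to uniform
        np.testing.assert_allclose(m.trans[0], [0, 1, 0, 0])
        np.testing.assert_allclose(m.trans[2], [0, 0, 0, 1])
        np.testing.assert_allclose(m.trans[1], [0.25] * 4)

    def test_unseen_words_uniform_transitions_zero_pi(self):
        m = fit_markov(_chrom("AAAA"), 1)
        assert m.pi[3] == 0
        np.testing.assert_allclose(m.trans[3], [0.25] * 4)

    def test_error_when_no_run_longer_than_k(self):
        with pytest.raises(ValueError, match="no unambiguous run"):
            fit_markov(_chrom("ACGNNACG"), 3)

    def test_refit_recovers_known_model(self):
        truth = preset_model("gc_skew", 2)
        tmpl = MaskedChromosome("t", np.zeros(400_000, dtype=np.uint8))
        sim = simulate_sequence(truth, tmpl, seed=7)
        fitted = fit_markov(sim, 2)
        n = 400_000
        se = np.sqrt(truth.pi * (1 - truth.pi) / n)
        assert (np.abs(fitted.pi - truth.pi) < 3 * se + 1e-9).all()
        # transition rows: binomial SE with per-row counts ~ n * pi
        for w in range(16):
            cnt = max(n * truth.pi[w], 1)
            se_t = np.sqrt(truth.trans[w] * (1 - truth.trans[w]) / cnt)
            assert (np.abs(fitted.trans[w] - truth.trans[w]) < 4 * se_t + 1e-9).all()


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        m = fit_markov(_chrom("ACGTACGTTGCANACGT"), 2)
        p = tmp_path / "model.json"
        m.to_json(p)
        back = MarkovModel.from_json(p)
        assert back.k == 2 and back.source == m.source
        np.testing.assert_allclose(back.pi, m.pi)
        np.testing.assert_allclose(back.trans, m.trans)

    def test_word_string_roundtrip(self):
        for k in (1, 3, 7):
            for w in (0, 4**k - 1, 4**k // 3):
                assert string_to_word(word_to_string(w, k)) == w

    def test_rc_permutation_is_involution(self):
        for k in (1, 2, 3, 5):
            rc = rc_permutation(k)
            np.testing.assert_array_equal(rc[rc], np.arange(4**k))
        assert rc_permutation(2)[string_to_word("AC")] == string_to_word("GT")


class TestPairProbability:
    def test_uniform_iid_closed_form(self):
        # sum_w pi(w) * P(rc(w)) = 4^k * 4^-k * 4^-k = 4^-k at every d
        for k in (1, 2):
            m = preset_model("uniform", k)
            pp = pair_probability(m, d_max=k + 6, horizon=3)
            np.testing.assert_allclose(pp.p, 0.25**k, atol=1e-12)

    def test_deterministic_complement_chain(self):
        trans = np.zeros((4, 4))
        trans[[0, 1, 2, 3], [3, 2, 1, 0]] = 1.0
        m = MarkovModel(1, np.full(4, 0.25), trans)
        pp = pair_probability(m, d_max=4, horizon=4)
        assert pp.p[0] == pytest.approx(1 - 1e-12)  # d = 1: next base complements
        assert pp.degenerate[0] and pp.degenerate[1]  # clipped at both ends

    def test_gc_skew_iid_closed_form(self):
        # i.i.d. chain: p(d) = (sum_b q_b q_{comp(b)})^k, independent of d
        m = preset_model("gc_skew", 2)
        expect = (2 * 0.3 * 0.3 + 2 * 0.2 * 0.2) ** 2
        pp = pair_probability(m, d_max=10, horizon=4)
        np.testing.assert_allclose(pp.p, expect, rtol=1e-12)

    def test_stationary_tail_matches_propagated_value(self):
        # fitted DNA-like chains mix fast: at the default horizon the exact
        # value and the stationary tail agree closely
        truth = preset_model("gc_skew", 2)
        sim = simulate_sequence(truth, MaskedChromosome("t", np.zeros(200_000, dtype=np.uint8)), 3)
        m = fit_markov(sim, 2)
        pp_long = pair_probability(m, d_max=100, horizon=60)
        assert abs(pp_long.p[58] - pp_long.p[70]) < 1e-6

    def test_reverse_complement_strand_invariance(self):
        # Inverted-repeat pairs map onto themselves on the opposite strand,
        # so p(d) under a stationary chain equals p(d) under the chain of
        # the reverse-complemented strand (built from the transformed
        # dinucleotide law Q'(a, b) = Q(comp b, comp a)).
        rng = np.random.default_rng(5)
        T = rng.random((4, 4)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(T.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi /= pi.sum()
        Q = pi[:, None] * T
        Qp = np.array([[Q[3 - b, 3 - a] for b in range(4)] for a in range(4)])
        pip = Qp.sum(axis=1)
        m_fwd = MarkovModel(1, pi, T)
        m_rev = MarkovModel(1, pip, Qp / pip[:, None])
        p_fwd = pair_probability(m_fwd, 8, horizon=8).p
        p_rev = pair_probability(m_rev, 8, horizon=8).p
        np.testing.assert_allclose(p_fwd, p_rev, atol=1e-12)

    def test_monte_carlo_agreement_small(self, rng):
        # small-scale version of the Monte-Carlo cross-check (the full one
        # runs in the acceptance suite)
        truth = preset_model("gc_skew", 2)
        sim = simulate_sequence(truth, MaskedChromosome("t", np.zeros(50_000, dtype=np.uint8)), 9)
        m = fit_markov(sim, 2)
        pp = pair_probability(m, d_max=6, horizon=10)
        n_mc = 200_000
        for d in (2, 4, 6):
            hits = _mc_pair_trials(m, d, n_mc, rng)
            p_hat = hits / n_mc
            se = np.sqrt(pp.p[d - 2] * (1 - pp.p[d - 2]) / n_mc)
            assert abs(p_hat - pp.p[d - 2]) < 3 * se + 1e-9


def _mc_pair_trials(model, d, n, rng):
    """Independent pair trials: draw word from pi, run the chain d steps,
    count how often the emitted k-mer is the start word's reverse complement."""
    k = model.k
    rc = rc_permutation(k)
    cum_pi = np.cumsum(model.pi)
    cum_tr = np.cumsum(model.trans, axis=1)
    state = np.searchsorted(cum_pi, rng.random(n), side="right").clip(0, 4**k - 1)
    start = state.copy()
    for _ in range(d):
        u = rng.random(n)
        b = (u[:, None] >= cum_tr[state]).sum(axis=1)
        state = (state % 4 ** (k - 1)) * 4 + b
    return int((state == rc[start]).sum())


class TestSimulate:
    def test_mask_preserved_exactly(self):
        tmpl = _chrom("ACNNACGTNA")
        out = simulate_sequence(preset_model("uniform", 2), tmpl, 1)
        np.testing.assert_array_equal(out.codes == 4, tmpl.codes == 4)
        assert out.length == tmpl.length

    def test_seed_determinism(self):
        tmpl = MaskedChromosome("t", np.zeros(5000, dtype=np.uint8))
        g = preset_model("gc_skew", 3)
        a = simulate_sequence(g, tmpl, 42)
        b = simulate_sequence(g, tmpl, 42)
        c = simulate_sequence(g, tmpl, 43)
        np.testing.assert_array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)

    def test_short_runs_filled_from_marginal(self):
        tmpl = _chrom("ACNACN")  # runs of length 2 < k = 3
        out = simulate_sequence(preset_model("uniform", 3), tmpl, 0)
        assert (out.codes[[0, 1, 3, 4]] < 4).all()

    def test_simulated_kmer_frequencies_match_model(self):
        # chi-square goodness of fit of 2-mer frequencies, alpha = 0.01
        truth = preset_model("gc_skew", 2)
        tmpl = MaskedChromosome("t", np.zeros(1_000_000, dtype=np.uint8))
        sim = simulate_sequence(truth, tmpl, 123)
        from irscape.counting import word_codes

        counts = np.bincount(word_codes(sim.codes.astype(np.int64), 2), minlength=16)
        expected = truth.pi * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=15)

    def test_all_zero_pi_rejected(self):
        m = preset_model("uniform", 1)
        m.pi = np.zeros(4)
        with pytest.raises(ValueError):
            simulate_sequence(m, _chrom("ACGT"), 0)
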