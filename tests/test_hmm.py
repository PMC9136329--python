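import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skelhmm import (
    DiscreteHMM,
    ObservationSequence,
    backward,
    baum_welch,
    forward,
    posteriors,
    random_hmm,
    sample,
    viterbi,
)
from oracles import enum_gamma, enum_likelihood, enum_viterbi


def obs(*symbols):
    return ObservationSequence(symbols=np.asarray(symbols))


class TestForwardBackward:
    def test_deterministic_model_gives_probability_one(self, det_hmm):
        assert forward(det_hmm, obs(1, 1)).log_likelihood == pytest.approx(0.0)
        assert backward(det_hmm, obs(1, 1)).log_likelihood == pytest.approx(0.0)

    def test_uniform_model_gives_half_power_T(self, uniform_hmm):
        for T in (1, 3, 7):
            o = obs(*([1] * T))
            assert forward(uniform_hmm, o).log_likelihood == pytest.approx(T * np.log(0.5))

    def test_impossible_sequence_is_minus_inf(self, det_hmm):
        assert forward(det_hmm, obs(1, 2)).log_likelihood == -np.inf

    def test_out_of_alphabet_symbol_errors(self, det_hmm):
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            forward(det_hmm, obs(1, 3))

    def test_backward_terminal_row_is_uniform_ones_scaled(self, uniform_hmm):
        res = backward(uniform_hmm, obs(1, 2, 1))
        # beta_T(i) = 1 for all i -> scaled row is uniform
        np.testing.assert_allclose(res.scaled[-1], [0.5, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10**6), N=st.integers(1, 3), M=st.integers(1, 3), T=st.integers(1, 6))
    def test_matches_path_enumeration(self, seed, N, M, T):
        rng = np.random.default_rng(seed)
        hmm = random_hmm(N, M, rng)
        o = obs(*(rng.integers(1, M + 1, size=T)))
        expected = enum_likelihood(hmm, o)
        for algo in (forward, backward):
            got = algo(hmm, o).log_likelihood
            assert got == pytest.approx(np.log(expected), rel=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10**6))
    def test_alpha_beta_product_constant_over_time(self, seed):
        """Sum_i alpha_t(i) beta_t(i) = P(O) at every t (scaled analogue:
        re-inflating the scaled rows reproduces a t-independent constant)."""
        rng = np.random.default_rng(seed)
        hmm = random_hmm(3, 3, rng)
        o = obs(*(rng.integers(1, 4, size=6)))
        fwd, bwd = forward(hmm, o), backward(hmm, o)
        T = len(o)
        lp = np.empty(T)
        for t in range(T):
            la = np.log(fwd.scaled[t]) + fwd.log_scale[: t + 1].sum()
            lb = np.log(bwd.scaled[t]) + bwd.log_scale[t + 1 :].sum()
            # unscaled beta also carries the termination factor of its own
            # normalizer at step t
            lb += bwd.log_scale[t]
            lp[t] = np.log(np.exp(la + lb).sum())
        np.testing.assert_allclose(lp, fwd.log_likelihood, rtol=1e-10)


class TestPosteriors:
    def test_single_state_gamma_is_one(self):
        hmm = DiscreteHMM(pi=[1.0], A=[[1.0]], B=[[0.3, 0.7]])
        post = posteriors(hmm, obs(1, 2, 2))
        np.testing.assert_allclose(post.gamma, 1.0)

    def test_deterministic_model_gamma_is_one_hot(self, det_hmm):
        post = posteriors(det_hmm, obs(1, 1, 1))
        np.testing.assert_allclose(post.gamma, np.tile([1.0, 0.0], (3, 1)))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10**6))
    def test_gamma_matches_enumeration_and_xi_marginals(self, seed):
        rng = np.random.default_rng(seed)
        hmm = random_hmm(3, 3, rng)
        o = obs(*(rng.integers(1, 4, size=5)))
        post = posteriors(hmm, o)
        np.testing.assert_allclose(post.gamma, enum_gamma(hmm, o), atol=1e-10)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-12)

    def test_mismatched_trellises_rejected(self, det_hmm, uniform_hmm):
        o = obs(1, 1)
        fwd = forward(det_hmm, o)
        with pytest.raises(ValueError):
            posteriors(det_hmm, o, fwd, fwd)  # two forward trellises
        with pytest.raises(ValueError):
            posteriors(det_hmm, obs(1, 1, 1), fwd, backward(det_hmm, o))


class TestViterbi:
    def test_deterministic_model_forced_path(self, det_hmm):
        res = viterbi(det_hmm, obs(1, 1, 1))
        np.testing.assert_array_equal(res.path, [1, 1, 1])
        assert res.log_prob == pytest.approx(0.0)

    def test_uniform_model_ties_to_lowest_state(self, uniform_hmm):
        res = viterbi(uniform_hmm, obs(1, 2, 1, 2))
        np.testing.assert_array_equal(res.path, [1, 1, 1, 1])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10**6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        hmm = random_hmm(3, 3, rng)
        o = obs(*(rng.integers(1, 4, size=5)))
        res = viterbi(hmm, o)
        path, p = enum_viterbi(hmm, o)
        assert res.log_prob == pytest.approx(np.log(p), rel=1e-10)
        np.testing.assert_array_equal(res.path, path)
        assert res.log_prob <= forward(hmm, o).log_likelihood + 1e-12


class TestBaumWelch:
    def test_single_state_emissions_converge_in_one_step(self):
        hmm0 = DiscreteHMM(pi=[1.0], A=[[1.0]], B=[[0.5, 0.5]])
        o = obs(1, 1, 2, 1)
        trained, _ = baum_welch(hmm0, [o], max_iter=1, floor=0.0)
        np.testing.assert_allclose(trained.B, [[0.75, 0.25]])

    def test_loglik_nondecreasing_and_rows_stochastic(self):
        rng = np.random.default_rng(11)
        gen = random_hmm(3, 4, rng)
        data = [sample(gen, 40, rng)[1] for _ in range(4)]
        trained, hist = baum_welch(random_hmm(3, 4, rng), data, max_iter=40, tol=0.0)
        assert np.all(np.diff(hist) >= -1e-9)
        assert trained.pi.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(trained.A.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(trained.B.sum(axis=1), 1.0, atol=1e-12)

    def test_two_state_parameter_recovery(self):
        truth = DiscreteHMM(
            pi=[0.6, 0.4],
            A=[[0.9, 0.1], [0.2, 0.8]],
            B=[[0.8, 0.15, 0.05], [0.05, 0.15, 0.8]],
        )
        rng = np.random.default_rng(42)
        data = [sample(truth, 200, rng)[1] for _ in range(50)]
        fit, hist = baum_welch(random_hmm(2, 3, 1), data, max_iter=200, tol=1e-6)
        assert np.all(np.diff(hist) >= -1e-9)

        def max_err(perm):
            idx = list(perm)
            return max(
                np.abs(fit.A[np.ix_(idx, idx)] - truth.A).max(),
                np.abs(fit.B[idx] - truth.B).max(),
                np.abs(fit.pi[idx] - truth.pi).max(),
            )

        assert min(max_err(p) for p in ([0, 1], [1, 0])) < 0.05

    def test_zero_probability_data_with_zero_floor_errors(self, det_hmm):
        with pytest.raises(ValueError, match="smoothing floor"):
            baum_welch(det_hmm, [obs(1, 2)], floor=0.0)

    def test_cross_check_against_hmmlearn(self):
        """Independent oracle: forward log-likelihood and one EM step agree
        with hmmlearn's CategoricalHMM on the same model and data."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(5)
        ours = random_hmm(3, 4, rng)
        seqs = [sample(ours, 30, rng)[1] for _ in range(3)]
        ref = hmmlearn.CategoricalHMM(n_components=3, init_params="")
        ref.startprob_, ref.transmat_, ref.emissionprob_ = ours.pi, ours.A, ours.B
        for o in seqs:
            ref_ll = ref.score((o.symbols - 1).reshape(-1, 1))
            assert forward(ours, o).log_likelihood == pytest.approx(ref_ll, rel=1e-10)


class TestSample:
    def test_deterministic_model_forces_output(self, det_hmm):
        states, o = sample(det_hmm, 5, seed=0)
        np.testing.assert_array_equal(states, [1] * 5)
        np.testing.assert_array_equal(o.symbols, [1] * 5)

    def test_same_seed_identical(self):
        hmm = random_hmm(3, 4, 9)
        s1, o1 = sample(hmm, 20, seed=123)
        s2, o2 = sample(hmm, 20, seed=123)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(o1.symbols, o2.symbols)

    def test_initial_state_frequencies_match_pi(self):
        hmm = DiscreteHMM(pi=[0.3, 0.7], A=np.eye(2), B=np.eye(2))
        rng = np.random.default_rng(77)
        n = 10_000
        firsts = np.array([sample(hmm, 1, rng)[0][0] for _ in range(n)])
        p_hat = (firsts == 1).mean()
        sigma = np.sqrt(0.3 * 0.7 / n)
        assert abs(p_hat - 0.3) < 3 * sigma


def test_serialization_round_trip():
    hmm = random_hmm(4, 5, 3)
    back = DiscreteHMM.from_json(hmm.to_json(metadata={"note": "x"}))
    np.testing.assert_allclose(back.pi, hmm.pi)
    np.testing.assert_allclose(back.A, hmm.A)
    np.testing.assert_allclose(back.B, hmm.B)


def test_invalid_model_rejected():
    with pytest.raises(ValueError):
        DiscreteHMM(pi=[0.5, 0.6], A=np.eye(2), B=np.eye(2))
    with pytest.raises(ValueError):
        DiscreteHMM(pi=[1.0, 0.0], A=[[1.0, 0.1], [0.0, 1.0]], B=np.eye(2))
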