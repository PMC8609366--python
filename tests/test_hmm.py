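import numpy as np
import pytest

from ofmri_states import (
    GaussianHMMVB,
    forward_backward,
    model_similarity,
    select_states,
    viterbi_path,
)
from oracles import brute_force_hmm, brute_force_viterbi, single_gaussian_vb_free_energy


def _random_chain(T, K, seed):
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    log_b = rng.normal(0.0, 2.0, size=(T, K))
    return log_b, A, pi


class TestForwardBackward:
    @pytest.mark.parametrize("T,K,seed", [(6, 2, 0), (6, 2, 1), (5, 3, 2), (8, 2, 3)])
    def test_matches_exhaustive_enumeration(self, T, K, seed):
        log_b, A, pi = _random_chain(T, K, seed)
        gamma, xi, lev = forward_backward(log_b, A, pi)
        g_ref, xi_ref, lev_ref = brute_force_hmm(log_b, A, pi)
        np.testing.assert_allclose(gamma, g_ref, atol=1e-10)
        np.testing.assert_allclose(xi, xi_ref, atol=1e-10)
        assert lev == pytest.approx(lev_ref, abs=1e-10)

    def test_single_state_degenerates_to_sum(self):
        log_b = np.array([[-1.0], [-2.0], [-0.5]])
        gamma, _, lev = forward_backward(log_b, np.ones((1, 1)), np.ones(1))
        np.testing.assert_array_equal(gamma, 1.0)
        assert lev == pytest.approx(log_b.sum())

    def test_uniform_everything_gives_uniform_gamma(self):
        K = 4
        gamma, _, _ = forward_backward(
            np.zeros((10, K)), np.full((K, K), 1.0 / K), np.full(K, 1.0 / K)
        )
        np.testing.assert_allclose(gamma, 1.0 / K, atol=1e-12)

    def test_no_underflow_on_long_sequences(self):
        rng = np.random.default_rng(0)
        log_b = rng.normal(-500, 30, size=(20000, 3))
        A = rng.dirichlet(np.ones(3), size=3)
        gamma, _, lev = forward_backward(log_b, A, np.ones(3) / 3)
        assert np.isfinite(lev)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_zero_row_rejected(self):
        A = np.array([[0.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="zero"):
            forward_backward(np.zeros((3, 2)), A, np.ones(2) / 2)


class TestViterbi:
    @pytest.mark.parametrize("T,K,seed", [(6, 2, 0), (6, 3, 1), (7, 2, 2)])
    def test_matches_exhaustive_argmax(self, T, K, seed):
        log_b, A, pi = _random_chain(T, K, seed)
        np.testing.assert_array_equal(
            viterbi_path(log_b, A, pi), brute_force_viterbi(log_b, A, pi)
        )

    def test_single_state_constant_path(self):
        path = viterbi_path(np.zeros((5, 1)), np.ones((1, 1)), np.ones(1))
        np.testing.assert_array_equal(path, 0)

    def test_ties_break_to_lower_index(self):
        K = 3
        path = viterbi_path(
            np.zeros((4, K)), np.full((K, K), 1.0 / K), np.full(K, 1.0 / K)
        )
        np.testing.assert_array_equal(path, 0)


def _two_state_stream(T=800, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    A = np.array([[0.95, 0.05], [0.05, 0.95]])
    z = np.empty(T, dtype=int)
    z[0] = 0
    for t in range(1, T):
        z[t] = rng.choice(2, p=A[z[t - 1]])
    X = np.where(z[:, None] == 0, -sep, sep) + rng.standard_normal((T, 2))
    return X, z


def _align_accuracy(pred, truth):
    return max((pred == truth).mean(), (pred != truth).mean())


class TestGaussianHMMVB:
    def test_k1_free_energy_matches_single_gaussian_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((300, 3)) * [1.0, 2.0, 0.5] + [0.3, -1.0, 0.0]
        model = GaussianHMMVB(n_states=1, random_state=0, cov_reg=0.0).fit(X)
        expected = single_gaussian_vb_free_energy(X, beta0=model.kappa_prior)
        assert model.free_energy_ == pytest.approx(expected, abs=1e-6)
        np.testing.assert_array_equal(model.gamma_, 1.0)

    def test_state_recovery_on_separated_stream(self):
        X, z = _two_state_stream(seed=1)
        model = GaussianHMMVB(n_states=2, random_state=0).fit(X)
        gamma_acc = _align_accuracy(model.gamma_.argmax(axis=1), z)
        vit_acc = _align_accuracy(model.predict(X), z)
        assert gamma_acc >= 0.95
        assert vit_acc >= gamma_acc - 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_free_energy_trace_monotone(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((400, 3)) + (rng.random((400, 1)) > 0.5) * 2.0
        model = GaussianHMMVB(n_states=3, random_state=seed, max_iter=60).fit(X)
        diffs = np.diff(model.free_energy_trace_)
        assert (diffs <= 1e-6).all()

    def test_gamma_rows_normalized(self):
        X, _ = _two_state_stream(T=300, seed=2)
        model = GaussianHMMVB(n_states=3, random_state=0).fit(X)
        np.testing.assert_allclose(model.gamma_.sum(axis=1), 1.0, atol=1e-8)
        assert (model.transmat_.sum(axis=1) == pytest.approx(1.0, abs=1e-10))

    def test_covariances_symmetric_pd(self):
        X, _ = _two_state_stream(T=300, seed=3)
        model = GaussianHMMVB(n_states=2, random_state=0).fit(X)
        for S in model.covariances_:
            np.testing.assert_allclose(S, S.T, atol=1e-10)
            assert np.linalg.eigvalsh(S).min() > 0

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            GaussianHMMVB(n_states=50).fit(np.random.default_rng(0).standard_normal((10, 2)))

    def test_lengths_partition_enforced(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="lengths"):
            GaussianHMMVB(n_states=2).fit(X, lengths=[4, 4])

    def test_multi_sequence_fit_isolates_runs(self):
        """Posterior on concatenated runs must not differ from feeding the
        same runs with explicit boundaries in gamma normalization."""
        X, _ = _two_state_stream(T=400, seed=4)
        model = GaussianHMMVB(n_states=2, random_state=0).fit(X, lengths=[200, 200])
        assert model.converged_
        np.testing.assert_allclose(model.gamma_.sum(axis=1), 1.0, atol=1e-8)

    def test_posterior_cross_check_against_ml_hmm(self):
        """With plenty of data the VB posterior state sequence agrees with an
        independent maximum-likelihood HMM (hmmlearn)."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        X, z = _two_state_stream(T=1000, seed=5)
        vb = GaussianHMMVB(n_states=2, random_state=0).fit(X)
        ml = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                  random_state=0, n_iter=50).fit(X)
        acc_vb = _align_accuracy(vb.gamma_.argmax(axis=1), z)
        acc_ml = _align_accuracy(ml.predict(X), z)
        assert abs(acc_vb - acc_ml) < 0.02


class TestModelSimilarity:
    def _fit(self, X, seed):
        return GaussianHMMVB(n_states=2, random_state=seed).fit(X)

    def test_self_similarity_is_one(self):
        X, _ = _two_state_stream(T=300, seed=6)
        m = self._fit(X, 0)
        assert model_similarity(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_label_permutation_invariance(self):
        X, _ = _two_state_stream(T=300, seed=7)
        m = self._fit(X, 0)
        permuted = m.gamma_[:, ::-1]
        assert model_similarity(m.gamma_, permuted) == pytest.approx(1.0, abs=1e-12)

    def test_independent_random_gammas_dissimilar(self):
        rng = np.random.default_rng(8)
        ga = rng.dirichlet(np.ones(14), size=2000)
        gb = rng.dirichlet(np.ones(14), size=2000)
        assert model_similarity(ga, gb) < 0.2

    def test_mismatched_lengths_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="time points"):
            model_similarity(
                rng.dirichlet(np.ones(3), size=10), rng.dirichlet(np.ones(3), size=11)
            )


class TestSelectStates:
    def test_chosen_rep_has_lowest_free_energy(self):
        X, _ = _two_state_stream(T=400, seed=10)
        report = select_states(X, K_list=(2, 3), reps=2, seed=0, max_iter=40)
        fes = report.free_energies[report.chosen_K]
        assert fes[report.chosen_rep] == min(fes)
        assert report.chosen_K == max(report.criterion, key=report.criterion.get)

    def test_reps_below_two_rejected(self):
        with pytest.raises(ValueError):
            select_states(np.zeros((10, 2)), K_list=(2,), reps=1)

    def test_failing_candidate_excluded_not_fatal(self):
        X, _ = _two_state_stream(T=30, seed=11)
        report = select_states(X, K_list=(2, 100), reps=2, seed=0, max_iter=20)
        assert 100 in report.excluded
        assert report.chosen_K == 2
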