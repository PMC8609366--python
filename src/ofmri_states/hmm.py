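"""Variational-Bayes hidden Markov model with Gaussian observation states.

Each hidden state k is a multivariate Gaussian over the (PCA-reduced) signal
space — its mean is the state's activation map and its covariance the state's
functional connectivity.  Inference is structured mean-field variational
Bayes: the posterior factorizes into the hidden path q(z) and the parameters
q(pi) q(A) q({mu_k, Lambda_k}), with conjugate priors

* symmetric Dirichlet(alpha0) on the initial distribution and on each
  transition-matrix row,
* Normal-Wishart on each state's (mean, precision): prior mean 0, scale
  kappa0 = 0.01, degrees of freedom d + 2, and a scale matrix matching the
  empirical per-dimension variances.

The free energy F = -ELBO decreases monotonically over iterations and is the
model-selection currency: the number of states is chosen by the ratio of
between-repetition model similarity to mean per-timepoint free energy.

Runs concatenated in time are handled as separate sequences via ``lengths``
(the chain is not propagated across run boundaries; the initial-state
posterior pools all run starts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# forward-backward and Viterbi (scaled domain; no underflow at T ~ 1e5)
# ---------------------------------------------------------------------------

def forward_backward(log_emission: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Posterior state marginals for one sequence.

    Parameters
    ----------
    log_emission : (T, K) ndarray
        Log emission scores.  For variational inference these are expected
        log densities; any finite values are accepted.
    A : (K, K) ndarray
        Non-negative transition scores.  Rows need not sum to one (variational
        subnormalized ``exp E[log A]`` is the intended use); a row summing to
        zero is an error.
    pi : (K,) ndarray
        Non-negative initial scores.

    Returns
    -------
    gamma : (T, K) posterior marginals, rows summing to 1
    xi_sum : (K, K) expected transition counts, summed over t
    log_evidence : float, the log normalizer of the chain
    """
    log_b = np.asarray(log_emission, dtype=float)
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    T, K = log_b.shape
    if np.any(A.sum(axis=1) <= 0):
        raise ValueError("transition matrix has a row summing to zero")
    if not np.all(np.isfinite(log_b)):
        raise ValueError("log emissions must be finite")

    offsets = log_b.max(axis=1)
    B = np.exp(log_b - offsets[:, None])  # row max = 1

    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        xi_sum += np.outer(alpha[t], bb) * A / c[t + 1]
        beta[t] = (A @ bb) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    log_evidence = float(np.log(c).sum() + offsets.sum())
    return gamma, xi_sum, log_evidence


def viterbi_path(log_emission: np.ndarray, A: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Most probable state path (log-domain max-product, ties to the lower
    state index)."""
    log_b = np.asarray(log_emission, dtype=float)
    with np.errstate(divide="ignore"):
        logA = np.log(np.asarray(A, dtype=float))
        logpi = np.log(np.asarray(pi, dtype=float))
    T, K = log_b.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=int)
    delta[0] = logpi + log_b[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax -> first (lowest) index
        delta[t] = cand[back[t], np.arange(K)] + log_b[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# conjugate-prior bookkeeping
# ---------------------------------------------------------------------------

def _dirichlet_expect_log(alpha: np.ndarray) -> np.ndarray:
    alpha = np.atleast_2d(alpha)
    return digamma(alpha) - digamma(alpha.sum(axis=1, keepdims=True))


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0)) summed over rows."""
    alpha = np.atleast_2d(alpha)
    alpha0 = np.broadcast_to(alpha0, alpha.shape)
    a_sum = alpha.sum(axis=1)
    a0_sum = alpha0.sum(axis=1)
    kl = (
        gammaln(a_sum)
        - gammaln(alpha).sum(axis=1)
        - gammaln(a0_sum)
        + gammaln(alpha0).sum(axis=1)
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_sum)[:, None])).sum(axis=1)
    )
    return float(kl.sum())


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdetW = np.linalg.slogdet(W)
    i = np.arange(1, d + 1)
    return float(
        -0.5 * nu * logdetW
        - 0.5 * nu * d * np.log(2.0)
        - 0.25 * d * (d - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu + 1 - i)).sum()
    )


def _wishart_elogdet(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    _, logdetW = np.linalg.slogdet(W)
    i = np.arange(1, d + 1)
    return float(digamma(0.5 * (nu + 1 - i)).sum() + d * np.log(2.0) + logdetW)


def _normal_wishart_kl(m, beta, W, nu, m0, beta0, W0, nu0) -> float:
    """KL( NW(m, beta, W, nu) || NW(m0, beta0, W0, nu0) )."""
    d = len(m)
    elogdet = _wishart_elogdet(W, nu)
    dm = m - m0
    quad = float(dm @ W @ dm)
    # E[ln q] - E[ln p], normal parts
    e_ln_q_mu = 0.5 * d * np.log(beta / (2 * np.pi)) + 0.5 * elogdet - 0.5 * d
    e_ln_p_mu = (
        0.5 * d * np.log(beta0 / (2 * np.pi))
        + 0.5 * elogdet
        - 0.5 * beta0 * (d / beta + nu * quad)
    )
    # Wishart parts
    entropy_q = (
        -_log_wishart_B(W, nu) - 0.5 * (nu - d - 1) * elogdet + 0.5 * nu * d
    )
    e_ln_p_lambda = (
        _log_wishart_B(W0, nu0)
        + 0.5 * (nu0 - d - 1) * elogdet
        - 0.5 * nu * np.trace(np.linalg.solve(W0, W))
    )
    return float(e_ln_q_mu - entropy_q - e_ln_p_mu - e_ln_p_lambda)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class GaussianHMMVB(BaseEstimator):
    """Variational-Bayes Gaussian-observation hidden Markov model.

    Parameters
    ----------
    n_states : int
        Number of hidden states K.
    max_iter : int
        Maximum variational EM iterations.
    tol : float
        Convergence threshold on the per-timepoint free-energy change:
        iteration stops when ``|delta F| < tol * T``.
    alpha_prior : float
        Symmetric Dirichlet concentration on pi and on each row of A.
    kappa_prior : float
        Prior scale (pseudo-counts) on each state mean.
    cov_reg : float
        Ridge added to each state's posterior scale matrix — a positive-
        definiteness floor for near-collapsed states.
    kmeans_subsample : int
        At most this many rows are used for the k-means initialization.
    random_state : int or None
        Seed for initialization.

    Attributes
    ----------
    means_ : (K, d) posterior mean activation maps (component space)
    covariances_ : (K, d, d) posterior expected state covariances
    transmat_ : (K, K) posterior-mean transition matrix (rows sum to 1)
    startprob_ : (K,) posterior-mean initial distribution
    gamma_ : (T, K) per-timepoint state activation probabilities
    xi_sum_ : (K, K) expected transition counts
    free_energy_trace_ : list of per-iteration free energies (monotone
        non-increasing; free energy = -ELBO, lower is better)
    free_energy_ : final free energy
    converged_ : bool
    collapsed_states_ : list of states whose total occupancy fell below one
        time point (kept, but flagged)
    """

    def __init__(
        self,
        n_states: int = 10,
        max_iter: int = 500,
        tol: float = 1e-6,
        alpha_prior: float = 1.0,
        kappa_prior: float = 0.01,
        cov_reg: float = 1e-6,
        kmeans_subsample: int = 10000,
        random_state=None,
    ):
        self.n_states = n_states
        self.max_iter = max_iter
        self.tol = tol
        self.alpha_prior = alpha_prior
        self.kappa_prior = kappa_prior
        self.cov_reg = cov_reg
        self.kmeans_subsample = kmeans_subsample
        self.random_state = random_state

    # -- internal -----------------------------------------------------------

    def _segments(self, T, lengths):
        if lengths is None:
            return [(0, T)]
        if sum(lengths) != T:
            raise ValueError(f"lengths sum to {sum(lengths)}, data has {T} rows")
        out, s = [], 0
        for L in lengths:
            out.append((s, s + L))
            s += L
        return out

    def _expected_log_emission(self, X):
        T, d = X.shape
        K = self.n_states
        log_b = np.empty((T, K))
        for k in range(K):
            Lw = self._W_chol[k]
            elogdet = self._elogdet[k]
            Y = (X - self._m[k]) @ Lw
            quad = np.einsum("ij,ij->i", Y, Y)
            log_b[:, k] = 0.5 * elogdet - 0.5 * d * _LOG2PI - 0.5 * (
                d / self._beta[k] + self._nu[k] * quad
            )
        return log_b

    def _m_step(self, X, gamma, xi_sum, start_counts):
        K = self.n_states
        T, d = X.shape
        Nk = gamma.sum(axis=0)
        self._alpha_A = self.alpha_prior + xi_sum
        self._alpha_pi = self.alpha_prior + start_counts
        self._m = np.empty((K, d))
        self._beta = np.empty(K)
        self._nu = np.empty(K)
        self._W_chol = np.empty((K, d, d))
        self._elogdet = np.empty(K)
        self._W = np.empty((K, d, d))
        for k in range(K):
            nk = Nk[k]
            if nk > 0:
                xbar = gamma[:, k] @ X / nk
                Xc = X - xbar
                Sk = (Xc.T * gamma[:, k]) @ Xc
            else:
                xbar = np.zeros(d)
                Sk = np.zeros((d, d))
            beta_k = self._beta0 + nk
            m_k = (self._beta0 * self._m0 + nk * xbar) / beta_k
            nu_k = self._nu0 + nk
            dm = xbar - self._m0
            Psi_k = (
                self._Psi0
                + Sk
                + (self._beta0 * nk / beta_k) * np.outer(dm, dm)
                + self.cov_reg * np.eye(d)
            )
            Psi_k = 0.5 * (Psi_k + Psi_k.T)
            W_k = np.linalg.inv(Psi_k)  # Wishart scale = inverse of IW scale
            W_k = 0.5 * (W_k + W_k.T)
            self._m[k] = m_k
            self._beta[k] = beta_k
            self._nu[k] = nu_k
            self._W[k] = W_k
            self._W_chol[k] = np.linalg.cholesky(W_k)
            self._elogdet[k] = _wishart_elogdet(W_k, nu_k)
        self._Nk = Nk

    def _free_energy_kl(self):
        kl = _dirichlet_kl(self._alpha_pi, np.full(self.n_states, self.alpha_prior))
        kl += _dirichlet_kl(self._alpha_A, np.full(self.n_states, self.alpha_prior))
        for k in range(self.n_states):
            kl += _normal_wishart_kl(
                self._m[k], self._beta[k], self._W[k], self._nu[k],
                self._m0, self._beta0, self._Psi0_inv, self._nu0,
            )
        return kl

    def _e_step(self, X, segments):
        log_b = self._expected_log_emission(X)
        A_star = np.exp(_dirichlet_expect_log(self._alpha_A))
        pi_star = np.exp(_dirichlet_expect_log(self._alpha_pi)).ravel()
        T = X.shape[0]
        gamma = np.empty((T, self.n_states))
        xi_sum = np.zeros((self.n_states, self.n_states))
        start_counts = np.zeros(self.n_states)
        log_evidence = 0.0
        for a, b in segments:
            g, xi, lz = forward_backward(log_b[a:b], A_star, pi_star)
            gamma[a:b] = g
            xi_sum += xi
            start_counts += g[0]
            log_evidence += lz
        return gamma, xi_sum, start_counts, log_evidence

    # -- public -------------------------------------------------------------

    def fit(self, X, y=None, lengths=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (time x components)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        T, d = X.shape
        K = int(self.n_states)
        if K < 1:
            raise ValueError("n_states must be >= 1")
        if K > T:
            raise ValueError(f"n_states = {K} exceeds number of time points {T}")
        segments = self._segments(T, lengths)

        # priors
        self._m0 = np.zeros(d)
        self._beta0 = float(self.kappa_prior)
        self._nu0 = float(d + 2)
        var = X.var(axis=0)
        self._Psi0 = np.diag(np.maximum(var, 1e-12))
        self._Psi0_inv = np.diag(1.0 / np.maximum(var, 1e-12))

        # k-means initialization on a seeded subsample
        rng = np.random.default_rng(self.random_state)
        if T > self.kmeans_subsample:
            idx = rng.choice(T, size=self.kmeans_subsample, replace=False)
            idx.sort()
        else:
            idx = np.arange(T)
        km_seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=K, n_init=5, random_state=km_seed).fit(X[idx])
        labels = km.predict(X)
        gamma = np.full((T, K), 0.1 / K)
        gamma[np.arange(T), labels] += 0.9
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi_sum = gamma[:-1].T @ gamma[1:]
        start_counts = np.zeros(K)
        for a, _ in segments:
            start_counts += gamma[a]
        self._m_step(X, gamma, xi_sum, start_counts)

        trace = []
        prev_F = np.inf
        self.converged_ = False
        for _ in range(int(self.max_iter)):
            gamma, xi_sum, start_counts, log_ev = self._e_step(X, segments)
            F = -(log_ev) + self._free_energy_kl()
            trace.append(F)
            if abs(prev_F - F) < self.tol * T:
                self.converged_ = True
                self._m_step(X, gamma, xi_sum, start_counts)
                break
            prev_F = F
            self._m_step(X, gamma, xi_sum, start_counts)

        self.gamma_ = gamma
        self.xi_sum_ = xi_sum
        self.free_energy_trace_ = trace
        self.free_energy_ = trace[-1]
        self.n_iter_ = len(trace)
        self.means_ = self._m.copy()
        self.covariances_ = np.array(
            [np.linalg.inv(self._W[k]) / (self._nu[k] - d - 1) for k in range(K)]
        )
        self.transmat_ = self._alpha_A / self._alpha_A.sum(axis=1, keepdims=True)
        self.startprob_ = (self._alpha_pi / self._alpha_pi.sum()).ravel()
        self.lengths_ = list(lengths) if lengths is not None else [T]
        self.n_features_in_ = d
        self.collapsed_states_ = [int(k) for k in np.where(self._Nk < 1.0)[0]]
        if self.collapsed_states_:
            logger.warning(
                "states %s collapsed (occupancy < 1 time point)", self.collapsed_states_
            )
        return self

    def predict_proba(self, X, lengths=None):
        """Per-timepoint state activation probabilities (gamma) for new data."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        segments = self._segments(X.shape[0], lengths)
        gamma, _, _, _ = self._e_step(X, segments)
        return gamma

    def predict(self, X, lengths=None):
        """Viterbi state path under the posterior-expected parameters."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        log_b = self._expected_log_emission(X)
        A_star = np.exp(_dirichlet_expect_log(self._alpha_A))
        pi_star = np.exp(_dirichlet_expect_log(self._alpha_pi)).ravel()
        segments = self._segments(X.shape[0], lengths)
        return np.concatenate(
            [viterbi_path(log_b[a:b], A_star, pi_star) for a, b in segments]
        )


# ---------------------------------------------------------------------------
# repetition similarity and model selection
# ---------------------------------------------------------------------------

def _as_gamma(model_or_gamma) -> np.ndarray:
    if hasattr(model_or_gamma, "gamma_"):
        return model_or_gamma.gamma_
    return np.asarray(model_or_gamma, dtype=float)


def model_similarity(model_a, model_b) -> float:
    """Similarity in [0, 1] between two fits of the same data.

    States are matched by maximum-weight bipartite assignment on the Pearson
    correlation between their gamma columns; the similarity is the mean of
    the matched correlations, with negative matches clipped to 0.
    """
    ga, gb = _as_gamma(model_a), _as_gamma(model_b)
    if ga.shape[0] != gb.shape[0]:
        raise ValueError("models were fit on different numbers of time points")
    if ga.shape[1] != gb.shape[1]:
        raise ValueError("models have different state counts")
    K = ga.shape[1]
    za = ga - ga.mean(axis=0)
    zb = gb - gb.mean(axis=0)
    sa = np.sqrt((za**2).sum(axis=0))
    sb = np.sqrt((zb**2).sum(axis=0))
    denom = np.outer(sa, sb)
    corr = np.zeros((K, K))
    ok = denom > 0
    corr[ok] = (za.T @ zb)[ok] / denom[ok]
    row, col = linear_sum_assignment(-corr)
    return float(np.clip(corr[row, col], 0.0, 1.0).mean())


def match_states(model_a, model_b):
    """Bipartite matching (rows of A to columns of B) on gamma correlation."""
    ga, gb = _as_gamma(model_a), _as_gamma(model_b)
    za = ga - ga.mean(axis=0)
    zb = gb - gb.mean(axis=0)
    sa = np.sqrt((za**2).sum(axis=0))
    sb = np.sqrt((zb**2).sum(axis=0))
    denom = np.outer(sa, sb)
    corr = np.zeros((ga.shape[1], gb.shape[1]))
    ok = denom > 0
    corr[ok] = (za.T @ zb)[ok] / denom[ok]
    row, col = linear_sum_assignment(-corr)
    return row, col, corr


@dataclass
class ModelSelectionReport:
    """Outcome of the similarity / free-energy model scan."""

    K_list: list[int]
    free_energies: dict = field(default_factory=dict)  # K -> list per rep
    similarities: dict = field(default_factory=dict)  # K -> mean pairwise
    criterion: dict = field(default_factory=dict)  # K -> similarity / (F/T)
    chosen_K: int = -1
    chosen_rep: int = -1
    models: dict = field(default_factory=dict)  # K -> list of fitted models
    excluded: dict = field(default_factory=dict)  # K -> reason

    @property
    def best_model(self):
        return self.models[self.chosen_K][self.chosen_rep]


def select_states(
    scores,
    K_list=(10, 12, 14, 16, 18),
    reps: int = 3,
    seed: int = 0,
    lengths=None,
    keep_models: bool = True,
    **fit_kwargs,
) -> ModelSelectionReport:
    """Scan state counts; pick the K maximizing similarity / free energy.

    For each candidate K the model is fit ``reps`` times from different
    seeded initializations.  The selection criterion is the mean pairwise
    between-repetition similarity divided by the mean *per-timepoint* free
    energy; the chosen repetition at the chosen K is the one with the lowest
    free energy.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2 to measure similarity")
    X = np.asarray(scores, dtype=float)
    T = X.shape[0]
    report = ModelSelectionReport(K_list=list(K_list))
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(K_list) * reps)]

    for i, K in enumerate(K_list):
        models, fes = [], []
        try:
            for r in range(reps):
                m = GaussianHMMVB(
                    n_states=K, random_state=rep_seeds[i * reps + r], **fit_kwargs
                ).fit(X, lengths=lengths)
                models.append(m)
                fes.append(m.free_energy_)
        except Exception as exc:  # noqa: BLE001 - any fit failure excludes K
            logger.warning("K = %d excluded from selection: %s", K, exc)
            report.excluded[K] = str(exc)
            continue
        sims = [
            model_similarity(models[a], models[b])
            for a in range(reps)
            for b in range(a + 1, reps)
        ]
        report.free_energies[K] = fes
        report.similarities[K] = float(np.mean(sims))
        report.criterion[K] = report.similarities[K] / (float(np.mean(fes)) / T)
        if keep_models:
            report.models[K] = models
    if not report.criterion:
        raise RuntimeError("every candidate state count failed to fit")
    report.chosen_K = max(report.criterion, key=report.criterion.get)
    report.chosen_rep = int(np.argmin(report.free_energies[report.chosen_K]))
    return report
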