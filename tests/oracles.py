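"""Independent reference implementations used only by the tests.

These deliberately use brute force or closed forms, not the package's own
algorithms, so that agreement is evidence of correctness rather than
self-consistency.
"""

import itertools

import numpy as np
from scipy.special import digamma, gammaln


def brute_force_hmm(log_emission, A, pi):
    """Exact posterior marginals by enumerating every state path.

    Feasible for T <= 8, K <= 3.  Returns (gamma, xi_sum, log_evidence).
    """
    log_b = np.asarray(log_emission, float)
    T, K = log_b.shape
    A = np.asarray(A, float)
    pi = np.asarray(pi, float)
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    Z = 0.0
    for path in itertools.product(range(K), repeat=T):
        w = pi[path[0]] * np.exp(log_b[0, path[0]])
        for t in range(1, T):
            w *= A[path[t - 1], path[t]] * np.exp(log_b[t, path[t]])
        Z += w
        for t in range(T):
            gamma[t, path[t]] += w
        for t in range(T - 1):
            xi[path[t], path[t + 1]] += w
    return gamma / Z, xi / Z, float(np.log(Z))


def brute_force_viterbi(log_emission, A, pi):
    """Exact most-probable path by enumeration (first in lexicographic order
    among ties, matching a lowest-index tie-break)."""
    log_b = np.asarray(log_emission, float)
    T, K = log_b.shape
    with np.errstate(divide="ignore"):
        logA = np.log(np.asarray(A, float))
        logpi = np.log(np.asarray(pi, float))
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + log_b[t, path[t]]
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return np.array(best)


def single_gaussian_vb_free_energy(X, beta0=0.01, cov_reg=0.0):
    """Variational free energy of one Gaussian fit to all of X under a
    Normal-Wishart prior (mean 0, scale beta0, dof d+2, scale matrix from
    the empirical per-dimension variances) — the closed-form K = 1 case.
    """
    X = np.asarray(X, float)
    T, d = X.shape
    m0 = np.zeros(d)
    nu0 = d + 2.0
    Psi0 = np.diag(np.maximum(X.var(axis=0), 1e-12))

    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    beta = beta0 + T
    m = (beta0 * m0 + T * xbar) / beta
    nu = nu0 + T
    dm = xbar - m0
    Psi = Psi0 + S + (beta0 * T / beta) * np.outer(dm, dm) + cov_reg * np.eye(d)
    W = np.linalg.inv(Psi)

    i = np.arange(1, d + 1)
    _, logdetW = np.linalg.slogdet(W)
    elogdet = digamma(0.5 * (nu + 1 - i)).sum() + d * np.log(2) + logdetW

    # expected log likelihood of each point
    Y = (X - m) @ np.linalg.cholesky(W)
    quad = (Y**2).sum(axis=1)
    e_loglik = (0.5 * elogdet - 0.5 * d * np.log(2 * np.pi)
                - 0.5 * (d / beta + nu * quad)).sum()

    def log_B(Wm, num):
        _, ld = np.linalg.slogdet(Wm)
        ii = np.arange(1, d + 1)
        return (-0.5 * num * ld - 0.5 * num * d * np.log(2)
                - 0.25 * d * (d - 1) * np.log(np.pi)
                - gammaln(0.5 * (num + 1 - ii)).sum())

    W0 = np.linalg.inv(Psi0)
    quad_m = float((m - m0) @ W @ (m - m0))
    e_ln_q_mu = 0.5 * d * np.log(beta / (2 * np.pi)) + 0.5 * elogdet - 0.5 * d
    e_ln_p_mu = (0.5 * d * np.log(beta0 / (2 * np.pi)) + 0.5 * elogdet
                 - 0.5 * beta0 * (d / beta + nu * quad_m))
    entropy_q = -log_B(W, nu) - 0.5 * (nu - d - 1) * elogdet + 0.5 * nu * d
    e_ln_p_lam = (log_B(W0, nu0) + 0.5 * (nu0 - d - 1) * elogdet
                  - 0.5 * nu * np.trace(np.linalg.solve(W0, W)))
    kl = e_ln_q_mu - entropy_q - e_ln_p_mu - e_ln_p_lam
    return float(-e_loglik + kl)


def tfce_plateau_closed_form(width, height, E=0.5, H=2.0):
    """Limit (n_steps -> inf) TFCE value of every sample of an isolated
    plateau: integral of width^E * h^H dh from 0 to height."""
    return width**E * height ** (H + 1) / (H + 1)


def ridge_closed_form(X, y, lam):
    """(X'X + lam I)^-1 X' y."""
    X = np.asarray(X, float)
    d = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(d), X.T @ y)
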