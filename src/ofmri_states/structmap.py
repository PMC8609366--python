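"""Structure-to-function mapping of state activation maps.

Two analyses relate a state's region-wise mean activation map to anatomy:

* **projection association** — Pearson correlation between the map and a
  single monosynaptic projection pattern (both rank-based inverse-normal
  transformed), with permutation FWE correction across the tested states;
* **connectome ridge prediction** — leave-one-out cross-validated ridge
  regression predicting the map from the full directed structural
  connectome, with the ridge penalty chosen per fold by an inner
  leave-one-out loop, out-of-sample Pearson rho (R^2 = rho^2), a deviance
  (residual sum of squares between standardized observed and predicted
  values), and a permutation p for the out-of-sample rho.  Fold-averaged
  coefficients, multiplied into the positive part of the connectome, give
  the directed circuit underlying the state.

Connectome convention: ``C[i, j]`` is the projection magnitude from source
region j to target region i, so rows are observations (targets) and columns
are predictors (sources).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

# default ridge-penalty grid for the inner loop.  The floor is deliberately
# well above zero: with a square predictor matrix whose columns are all
# rank-inverse-normal transformed (identical marginal quantiles), penalties
# near zero put leave-one-out ridge in an interpolating regime that can
# reproduce *any* permutation of the response almost exactly, which inflates
# the permutation null and destroys power.  Penalties >= 0.1 keep the fit in
# the regularized regime where out-of-sample correlation is meaningful.
DEFAULT_LAMBDA_GRID = np.logspace(-1, 3, 25)


def rank_inverse_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    Ranks (ties to average rank) are mapped through the standard-normal
    quantile of ``(r - c) / (n + 1 - 2c)`` with the Blom constant c = 3/8.
    All-equal input has undefined ranks and is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        raise ValueError("all-equal input: rank transform undefined")
    r = rankdata(x, method="average")
    return ndtri((r - c) / (x.size + 1 - 2 * c))


def projection_association(
    projection: np.ndarray,
    state_maps: np.ndarray,
    nperm: int = 1000,
    seed: int = 0,
    rank_transform: bool = True,
):
    """Correlation between a projection pattern and one or more state maps.

    Returns ``(r, p_fwe)``; with several maps the null is the maximum |r|
    across maps under permutation of the region assignment, giving FWE
    control over the family of tested states.
    """
    proj = np.asarray(projection, dtype=float)
    maps = np.atleast_2d(np.asarray(state_maps, dtype=float))
    if maps.shape[1] != proj.size:
        raise ValueError("projection and maps must share the region axis")
    if rank_transform:
        proj = rank_inverse_normal(proj)
        maps = np.stack([rank_inverse_normal(m) for m in maps])
    pz = (proj - proj.mean()) / proj.std()
    mz = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    n = proj.size
    r_obs = mz @ pz / n

    rng = np.random.default_rng(seed)
    null_max = np.empty(nperm)
    for p in range(nperm):
        perm = rng.permutation(n)
        null_max[p] = np.abs(mz @ pz[perm] / n).max()
    p_fwe = (1 + (null_max[:, None] >= np.abs(r_obs)[None]).sum(axis=0)) / (nperm + 1)
    if np.ndim(state_maps) == 1:
        return float(r_obs[0]), float(p_fwe[0])
    return r_obs, p_fwe


@dataclass
class RidgeMapResult:
    """Leave-one-out ridge prediction of a state map from a connectome."""

    fold_betas: np.ndarray  # (n_predictors, n_folds)
    mean_betas: np.ndarray  # fold average
    predictions: np.ndarray  # out-of-sample, one per region
    observed: np.ndarray  # the (transformed) response
    lambdas: np.ndarray  # selected penalty per fold
    rho: float
    r2: float
    deviance: float
    p_value: float
    nperm: int


def _zscore(v):
    return (v - v.mean()) / v.std()


def _fold_cache(X: np.ndarray, lambda_grid: np.ndarray):
    """Per-fold SVD quantities reused across the observed fit and every
    permutation (the design never changes under response permutation)."""
    n = X.shape[0]
    cache = []
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        U, s, Vt = np.linalg.svd(X[tr], full_matrices=False)
        s2 = s**2
        f = s2[None, :] / (s2[None, :] + lambda_grid[:, None])  # (L, r)
        g = s[None, :] / (s2[None, :] + lambda_grid[:, None])
        h = (U**2) @ f.T  # (n-1, L) inner-LOO leverages
        one_minus_h = 1.0 - h
        if np.any(one_minus_h < 1e-8):
            logger.warning(
                "fold %d: inner leverage ~1 at small penalties; flooring", i
            )
            one_minus_h = np.maximum(one_minus_h, 1e-8)
        wv = Vt @ X[i]  # (r,)
        cache.append(dict(tr=tr, U=U, Vt=Vt, f=f, g=g, omh=one_minus_h, wv=wv))
    return cache


def _loo_predict(cache, Y: np.ndarray, lambda_grid: np.ndarray, want_betas: bool):
    """Out-of-sample predictions for every response column of Y (n, P),
    selecting the inner-loop penalty per fold and per column."""
    n, P = Y.shape
    L = len(lambda_grid)
    preds = np.empty((n, P))
    lambdas = np.empty(n)
    betas = np.empty((cache[0]["Vt"].shape[1], n)) if want_betas else None
    for i, fc in enumerate(cache):
        Ytr = Y[fc["tr"]]  # (n-1, P)
        Z = fc["U"].T @ Ytr  # (r, P)
        mse = np.empty((L, P))
        for li in range(L):
            Yhat = fc["U"] @ (fc["f"][li][:, None] * Z)
            E = (Ytr - Yhat) / fc["omh"][:, li][:, None]
            mse[li] = np.mean(E**2, axis=0)
        best = np.argmin(mse, axis=0)  # (P,) — ties to the smaller penalty
        M = fc["g"] * fc["wv"][None, :]  # (L, r)
        predmat = M @ Z  # (L, P)
        preds[i] = predmat[best, np.arange(P)]
        lambdas[i] = lambda_grid[best[0]]
        if want_betas:
            betas[:, i] = fc["Vt"].T @ (fc["g"][best[0]] * Z[:, 0])
    return preds, lambdas, betas


class LooRidgeMapper(BaseEstimator):
    """Leave-one-out ridge prediction of a region map from a connectome.

    Parameters
    ----------
    lambda_grid : array-like
        Candidate ridge penalties; the inner leave-one-out loop picks, for
        each outer fold, the penalty minimizing inner prediction MSE.
    nperm : int
        Permutations of the response for the significance of the
        out-of-sample rho.
    mask_diagonal : bool
        Zero the connectome diagonal (self-projections) before use.
    rank_transform : bool
        Apply the rank-based inverse normal transform to every predictor
        column and to the response (the convention of this pipeline).

    Attributes (after fit)
    ----------------------
    result_ : RidgeMapResult
    rho_, r2_, deviance_, p_value_ : floats, copied from ``result_``
    """

    def __init__(
        self,
        lambda_grid=None,
        nperm: int = 1000,
        seed: int = 0,
        mask_diagonal: bool = False,
        rank_transform: bool = True,
    ):
        self.lambda_grid = lambda_grid
        self.nperm = nperm
        self.seed = seed
        self.mask_diagonal = mask_diagonal
        self.rank_transform = rank_transform

    def fit(self, C, y):
        grid = np.sort(np.asarray(
            DEFAULT_LAMBDA_GRID if self.lambda_grid is None else self.lambda_grid,
            dtype=float,
        ))
        C = np.asarray(C, dtype=float)
        y = np.asarray(y, dtype=float)
        n = y.size
        if C.shape[0] != n:
            raise ValueError("connectome rows must match the response length")
        if self.mask_diagonal and C.shape[0] == C.shape[1]:
            C = C.copy()
            np.fill_diagonal(C, 0.0)
        if self.rank_transform:
            X = np.column_stack([rank_inverse_normal(C[:, j]) for j in range(C.shape[1])])
            yt = rank_inverse_normal(y)
        else:
            X, yt = C, y

        rng = np.random.default_rng(self.seed)
        Y = np.empty((n, self.nperm + 1))
        Y[:, 0] = yt
        for p in range(self.nperm):
            Y[:, p + 1] = yt[rng.permutation(n)]

        cache = _fold_cache(X, grid)
        preds, lambdas, betas = _loo_predict(cache, Y, grid, want_betas=True)

        yz = _zscore(Y[:, 0])
        pz = preds - preds.mean(axis=0)
        denom = np.sqrt((pz**2).sum(axis=0)) * np.sqrt(n)
        denom[denom == 0] = np.inf
        rhos = np.array([
            float(np.dot(_zscore(Y[:, p]), pz[:, p]) / denom[p]) if denom[p] < np.inf else 0.0
            for p in range(self.nperm + 1)
        ])
        rho = rhos[0]
        p_value = float((1 + (rhos[1:] >= rho).sum()) / (self.nperm + 1))
        deviance = float(np.sum((yz - _zscore(preds[:, 0])) ** 2)) if preds[:, 0].std() > 0 else float("nan")
        self.result_ = RidgeMapResult(
            fold_betas=betas,
            mean_betas=betas.mean(axis=1),
            predictions=preds[:, 0],
            observed=Y[:, 0],
            lambdas=lambdas,
            rho=float(rho),
            r2=float(rho**2),
            deviance=deviance,
            p_value=p_value,
            nperm=self.nperm,
        )
        self.rho_ = self.result_.rho
        self.r2_ = self.result_.r2
        self.deviance_ = self.result_.deviance
        self.p_value_ = self.result_.p_value
        self.n_features_in_ = X.shape[1]
        return self


def loo_ridge_map(
    C,
    y,
    lambda_grid=None,
    nperm: int = 1000,
    seed: int = 0,
    mask_diagonal: bool = False,
    rank_transform: bool = True,
) -> RidgeMapResult:
    """Functional wrapper over :class:`LooRidgeMapper`."""
    est = LooRidgeMapper(
        lambda_grid=lambda_grid,
        nperm=nperm,
        seed=seed,
        mask_diagonal=mask_diagonal,
        rank_transform=rank_transform,
    ).fit(C, y)
    return est.result_


def circuit_from_betas(result: RidgeMapResult, C: np.ndarray) -> np.ndarray:
    """Directed circuit underlying a predicted map.

    Each column j (source region) of the connectome is scaled by the
    fold-averaged coefficient beta_j; entries <= 0 are set to zero (only
    positive connections are interpreted).
    """
    C = np.asarray(C, dtype=float)
    circuit = C * result.mean_betas[None, :]
    return np.where(circuit > 0, circuit, 0.0)


def map_difference(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Elementwise difference of two aligned state maps, rank-inverse-normal
    transformed (the response for predicting between-state differences)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must be aligned")
    return rank_inverse_normal(a - b)
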