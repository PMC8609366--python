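"""PCA to a target explained-variance fraction, with state back-projection.

The state-decoding pipeline reduces the concatenated, per-run-standardized
region time series to the smallest number of principal components whose
cumulative explained-variance ratio reaches a target fraction (0.5 by
default).  State parameters inferred in component space are later
back-projected: a component-space mean becomes a region mean-activation map,
and a component-space covariance becomes a region functional-connectivity
matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class VarianceFractionPCA(TransformerMixin, BaseEstimator):
    """PCA retaining the fewest components reaching a variance fraction.

    Components are computed by eigendecomposition of the covariance of the
    (centered) input, with deterministic ordering and a fixed sign
    convention: each loading's largest-magnitude element is made positive.

    Parameters
    ----------
    variance_fraction : float in (0, 1]
        Target cumulative explained-variance ratio.  The number of retained
        components ``m`` is the smallest count whose cumulative ratio is
        >= this fraction.

    Attributes
    ----------
    components_ : (m, n_regions) ndarray
        Orthonormal loadings, one row per retained component.
    explained_variance_ratio_ : (n_regions,) ndarray
        Ratios for *all* components, non-increasing.
    mean_ : (n_regions,) ndarray
        Per-feature mean removed before projection.
    n_components_ : int
    """

    def __init__(self, variance_fraction: float = 0.5):
        self.variance_fraction = variance_fraction

    def fit(self, X, y=None):
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ValueError(
                f"variance_fraction must be in (0, 1], got {self.variance_fraction}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-D with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        cov = (Xc.T @ Xc) / X.shape[0]
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals, kind="stable")[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # sign convention: largest-magnitude element of each loading positive
        flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])])
        flip[flip == 0] = 1.0
        evecs = evecs * flip

        total = evals.sum()
        if total <= 0:
            raise ValueError("input has zero variance")
        ratios = evals / total
        cum = np.cumsum(ratios)
        m = int(np.searchsorted(cum, self.variance_fraction - 1e-12) + 1)
        m = min(m, len(evals))

        self.explained_variance_ = evals
        self.explained_variance_ratio_ = ratios
        self.components_ = evecs[:, :m].T
        self.n_components_ = m
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self)
        return np.asarray(scores) @ self.components_ + self.mean_

    def backproject_state(self, mean_c, cov_c, add_mean: bool = False):
        """Back-project component-space state parameters to region space.

        Returns ``(region_mean_map, region_connectivity)``:
        ``loadings.T @ mean`` (plus the training mean if ``add_mean``) and the
        symmetric ``loadings.T @ cov @ loadings``.
        """
        check_is_fitted(self)
        mean_c = np.asarray(mean_c, dtype=float)
        cov_c = np.asarray(cov_c, dtype=float)
        m = self.n_components_
        if mean_c.shape != (m,) or cov_c.shape != (m, m):
            raise ValueError(
                f"expected mean ({m},) and covariance ({m}, {m}); got "
                f"{mean_c.shape} and {cov_c.shape}"
            )
        L = self.components_  # (m, R)
        mean_map = L.T @ mean_c
        if add_mean:
            mean_map = mean_map + self.mean_
        conn = L.T @ cov_c @ L
        conn = 0.5 * (conn + conn.T)
        return mean_map, conn

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self)
        payload = dict(
            variance_fraction=self.variance_fraction,
            n_components=self.n_components_,
            mean=self.mean_.tolist(),
            explained_variance_ratio=self.explained_variance_ratio_.tolist(),
            components=self.components_.tolist(),
        )
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "VarianceFractionPCA":
        d = json.loads(Path(path).read_text())
        est = cls(variance_fraction=d["variance_fraction"])
        est.mean_ = np.asarray(d["mean"])
        est.explained_variance_ratio_ = np.asarray(d["explained_variance_ratio"])
        est.explained_variance_ = est.explained_variance_ratio_  # ratios only on disk
        est.components_ = np.asarray(d["components"])
        est.n_components_ = int(d["n_components"])
        est.n_features_in_ = est.components_.shape[1]
        return est


def pca_reduce(concat, variance_fraction: float = 0.5):
    """Fit :class:`VarianceFractionPCA` on concatenated data and project it.

    Returns ``(model, scores)`` with scores of shape (total_time, m).
    """
    X = concat.data if hasattr(concat, "data") else np.asarray(concat)
    model = VarianceFractionPCA(variance_fraction=variance_fraction).fit(X)
    return model, model.transform(X)
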