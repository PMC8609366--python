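"""Static general-linear-model baseline on ROI time series.

The conventional comparison analysis: the stimulation boxcar convolved with a
single-gamma HRF, plus its first temporal derivative, regressed against each
region's BOLD signal by ordinary least squares.  Permutation significance
uses circular shifts of the stimulus regressor — which preserve the temporal
autocorrelation of the data under the null — with max-|t| correction across
regions.  By construction this yields one static activation map per
condition; resolving temporally overlapping dynamic states is exactly what it
cannot do, which is the contrast motivating the HMM analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import convolve_boxcar, gamma_hrf
from .io import RoiTimeSeries
from .paradigm import StimulationParadigm


@dataclass
class GlmDesign:
    """Design matrix [HRF regressor, its temporal derivative, intercept,
    covariates...] with the HRF parameters that built it."""

    matrix: np.ndarray
    columns: list[str]
    hrf_mean_lag_s: float = 6.0
    hrf_dispersion_s: float = 3.0

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


def build_design(
    paradigm: StimulationParadigm,
    hrf_mean_lag_s: float = 6.0,
    hrf_dispersion_s: float = 3.0,
    covariates: np.ndarray | None = None,
) -> GlmDesign:
    """HRF-convolved boxcar + first temporal difference + intercept
    (+ optional nuisance covariates, e.g. motion parameters)."""
    box = paradigm.boxcar()
    kernel = gamma_hrf(paradigm.tr_s, hrf_mean_lag_s, hrf_dispersion_s)
    reg = convolve_boxcar(box, kernel)
    dreg = np.diff(reg, prepend=reg[0])
    cols = [reg, dreg, np.ones_like(reg)]
    names = ["hrf", "hrf_derivative", "intercept"]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(reg):
            covariates = covariates.T
        for i in range(covariates.shape[1]):
            cols.append(covariates[:, i])
            names.append(f"cov{i}")
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    return GlmDesign(matrix=X, columns=names,
                     hrf_mean_lag_s=hrf_mean_lag_s, hrf_dispersion_s=hrf_dispersion_s)


@dataclass
class GlmFit:
    betas: np.ndarray  # (p, n_regions)
    t_hrf: np.ndarray  # (n_regions,) t for the HRF regressor
    dof: int
    columns: list[str] = field(default_factory=list)


def fit_glm(run: RoiTimeSeries | np.ndarray, design: GlmDesign) -> GlmFit:
    """OLS fit of the design to every region; t = beta/SE for the HRF
    regressor with residual dof n - p."""
    Y = run.data if isinstance(run, RoiTimeSeries) else np.asarray(run, dtype=float)
    X = design.matrix
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"data has {Y.shape[0]} rows, design {n}")
    if n <= p:
        raise ValueError("need more time points than regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns involved in the collinearity
        bad = []
        for j in range(p):
            others = np.delete(np.arange(p), j)
            if np.linalg.matrix_rank(X[:, others]) == rank:
                bad.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # (p, R)
    resid = Y - X @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 1e-300))
    return GlmFit(betas=B, t_hrf=B[0] / se, dof=dof, columns=list(design.columns))


def perm_glm(
    runs,
    paradigm: StimulationParadigm,
    nperm: int = 1000,
    seed: int = 0,
    hrf_mean_lag_s: float = 6.0,
    hrf_dispersion_s: float = 3.0,
    covariates=None,
) -> dict:
    """FWE p per region for the HRF response, pooled over runs.

    The group statistic per region is the mean over runs of the per-run t
    value.  The null shifts the stimulus regressor circularly by a random
    offset (at least one block period away from zero, the same offset for
    every run within a permutation) and refits.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    if isinstance(runs, (RoiTimeSeries, np.ndarray)):
        runs = [runs]
    if not runs:
        raise ValueError("need at least one run")
    rng = np.random.default_rng(seed)

    def stat_for(design):
        return np.mean([fit_glm(r, design).t_hrf for r in runs], axis=0)

    base = build_design(paradigm, hrf_mean_lag_s, hrf_dispersion_s, covariates)
    observed = stat_for(base)

    period = int(round((paradigm.on_s + paradigm.off_s) / paradigm.tr_s))
    T = paradigm.n_volumes
    lo, hi = period, T - period
    if hi <= lo:
        lo, hi = 1, T
    null_max = np.empty(nperm)
    reg = base.matrix[:, 0]
    dreg = base.matrix[:, 1]
    for p in range(nperm):
        shift = int(rng.integers(lo, hi))
        Xs = base.matrix.copy()
        Xs[:, 0] = np.roll(reg, shift)
        Xs[:, 1] = np.roll(dreg, shift)
        design_s = GlmDesign(Xs, base.columns, hrf_mean_lag_s, hrf_dispersion_s)
        null_max[p] = np.abs(stat_for(design_s)).max()
    p_fwe = (1 + (null_max[:, None] >= np.abs(observed)[None]).sum(axis=0)) / (nperm + 1)
    return dict(t=observed, p_fwe=p_fwe, nperm=nperm)
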