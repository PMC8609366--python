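"""Permutation inference on evoked state curves.

All tests share one recipe: a pointwise statistic over the (state x window)
family of evoked activation-probability curves, one-dimensional threshold-free
cluster enhancement (TFCE) along the window axis, and family-wise error (FWE)
control by the maximum enhanced statistic across time *and* states under a
permutation null.  p-values use the (1 + #{perm max >= observed}) / (nperm + 1)
convention, so the smallest attainable p with 1,000 permutations is ~0.001.

Exchangeability:

* group comparisons permute subject group labels (the exchangeable unit is
  the subject-level curve — the median across a subject's runs — which avoids
  pseudoreplication of runs within subject);
* the within-subject frequency ANOVA treats each session (one run per
  frequency) as an exchangeability block: frequency labels are shuffled
  within each session, and whole sessions may be swapped (which leaves the
  one-sample statistics invariant);
* the group-by-frequency interaction permutes group labels across subjects
  after reducing each subject to its frequency-contrast curves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

@dataclass
class TfceParams:
    """1-D TFCE parameters: extent exponent E, height exponent H, number of
    integration steps (dh = max(curve)/n_steps)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def tfce1d(curve: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1-D statistic curve.

    Negative values are treated as zero (one-sided; the opposite contrast
    covers the other tail).  For each position the enhanced value is
    sum over thresholds h = dh, 2dh, ..., max(curve) of
    extent(h)^E * h^H * dh, where extent is the length in samples of the
    contiguous supra-threshold run containing the position.
    """
    params = params or TfceParams()
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1:
        raise ValueError("tfce1d expects a 1-D curve")
    if not np.all(np.isfinite(c)):
        raise ValueError("curve must be finite")
    return tfce1d_batch(c[None, :], params)[0]


def tfce1d_batch(curves: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """Vectorized :func:`tfce1d` over the rows of a (n, W) array."""
    params = params or TfceParams()
    C = np.maximum(np.asarray(curves, dtype=float), 0.0)
    n, W = C.shape
    mx = C.max(axis=1)
    out = np.zeros_like(C)
    active = mx > 0
    if not active.any():
        return out
    dh = mx / params.n_steps  # per-curve step
    rows = np.arange(n)[:, None]
    counts = np.empty((n, W // 2 + 2), dtype=float)
    for step in range(1, params.n_steps + 1):
        h = step * dh  # (n,)
        mask = C >= h[:, None]
        mask &= active[:, None]
        if not mask.any():
            continue
        starts = mask.copy()
        starts[:, 1:] &= ~mask[:, :-1]
        rid = np.cumsum(starts, axis=1) * mask  # run ids 1.. within each row
        counts[:] = 0.0
        np.add.at(counts, (np.broadcast_to(rows, rid.shape), rid), mask)
        extent = counts[rows.ravel()[:, None], rid]
        out += np.where(
            mask, extent**params.E * (h[:, None] ** params.H) * dh[:, None], 0.0
        )
    return out


# ---------------------------------------------------------------------------
# results container and contrasts
# ---------------------------------------------------------------------------

@dataclass
class PermResult:
    """Observed statistic curves, their TFCE enhancement, and FWE p-values,
    all of shape (K states, W window samples)."""

    observed: np.ndarray
    enhanced: np.ndarray
    p_fwe: np.ndarray
    nperm: int
    scheme: str = ""
    contrast: str = ""

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_fwe <= alpha

    def min_p(self) -> np.ndarray:
        """Minimum FWE p per state."""
        return self.p_fwe.min(axis=1)


@dataclass
class ContrastSpec:
    """Weights over the frequency levels (5, 10, 20 Hz by convention).

    A plain contrast tests one weighted combination.  A *conjunction*
    contrast (``steps`` given) tests a strict monotonic ordering: the
    statistic is the elementwise minimum of the one-sample t's of each step
    contrast, so every step must be positive for the curve to be enhanced —
    distinguishing a true monotone profile from single-frequency tuning,
    which a single linear trend contrast cannot do.
    """

    label: str
    weights: tuple
    sidedness: str = "greater"  # enhanced tail: positive statistic values
    steps: tuple | None = None  # conjunction of step contrasts

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum()) > 1e-10:
            raise ValueError(f"contrast '{self.label}' weights must sum to 0, got {w}")
        self.weights = tuple(w)


CONTRAST_5HZ = ContrastSpec("5Hz>10,20Hz", (1.0, -0.5, -0.5))
CONTRAST_10HZ = ContrastSpec("10Hz>5,20Hz", (-0.5, 1.0, -0.5))
CONTRAST_20HZ = ContrastSpec("20Hz>5,10Hz", (-0.5, -0.5, 1.0))
CONTRAST_INCREASING = ContrastSpec(
    "5Hz<10Hz<20Hz", (-1.0, 0.0, 1.0),
    steps=((-1.0, 1.0, 0.0), (0.0, -1.0, 1.0)),
)
CONTRAST_DECREASING = ContrastSpec(
    "5Hz>10Hz>20Hz", (1.0, 0.0, -1.0),
    steps=((1.0, -1.0, 0.0), (0.0, 1.0, -1.0)),
)
THETA_CONTRASTS = (CONTRAST_5HZ, CONTRAST_10HZ)


def _as_curve_stack(responses) -> np.ndarray:
    """(n, K, W) array from a list of EvokedResponse or an array."""
    if hasattr(responses, "__len__") and len(responses) and hasattr(responses[0], "curves"):
        return np.stack([r.curves for r in responses])
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n, K, W) curves")
    return arr


def _fwe_p(enhanced_all: np.ndarray, n_effective: int | None = None) -> np.ndarray:
    """FWE p-curves from enhanced statistics, observed first.

    ``enhanced_all``: (nperm+1, K, W) with index 0 the observed map.  The
    null maximum is taken over states and window samples jointly.
    """
    obs = enhanced_all[0]
    null_max = enhanced_all[1:].reshape(enhanced_all.shape[0] - 1, -1).max(axis=1)
    # observed counted once in numerator and denominator
    count = 1 + (null_max[:, None, None] >= obs[None]).sum(axis=0)
    denom = (len(null_max) + 1) if n_effective is None else n_effective
    return count / denom


def _two_sample_t(
    X: np.ndarray, G1: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Pooled-variance two-sample t for many label assignments at once.

    X : (n, F) flattened curves; G1 : (P, n) 0/1 membership of group 1.
    Returns (P, F).
    """
    G2 = 1.0 - G1
    s1 = G1 @ X
    s2 = G2 @ X
    q1 = G1 @ (X**2)
    q2 = G2 @ (X**2)
    m1 = s1 / n1
    m2 = s2 / n2
    ss = (q1 - n1 * m1**2) + (q2 - n2 * m2**2)
    sp2 = ss / (n1 + n2 - 2)
    denom = np.sqrt(np.maximum(sp2 * (1.0 / n1 + 1.0 / n2), VAR_FLOOR))
    return (m1 - m2) / denom


def _group_label_perms(n: int, n1: int, nperm: int, rng) -> tuple[np.ndarray, int | None]:
    """(P+1, n) 0/1 membership matrices, observed assignment first.

    If the number of distinct assignments does not exceed nperm, all of them
    are enumerated (observed included) and exact p-values are used.
    """
    n_distinct = comb(n, n1)
    observed = np.zeros(n)
    observed[:n1] = 1.0
    if n_distinct <= nperm:
        G = np.zeros((n_distinct, n))
        for i, ix in enumerate(itertools.combinations(range(n), n1)):
            G[i, list(ix)] = 1.0
        # move the observed assignment to the front
        obs_row = int(np.where((G == observed).all(axis=1))[0][0])
        G[[0, obs_row]] = G[[obs_row, 0]]
        return G, n_distinct
    G = np.zeros((nperm + 1, n))
    G[0] = observed
    for p in range(1, nperm + 1):
        G[p, rng.choice(n, size=n1, replace=False)] = 1.0
    return G, None


# ---------------------------------------------------------------------------
# group difference test
# ---------------------------------------------------------------------------

def group_difference_test(
    group1,
    group2,
    direction: str = "greater",
    tfce_params: TfceParams | None = None,
    nperm: int = 1000,
    seed: int = 0,
    scheme: str = "subject-label permutation",
) -> PermResult:
    """FWE-corrected two-sample test on subject-level evoked curves.

    Tests group1 > group2 pointwise (``direction="greater"``; pass "less"
    for the opposite tail), with TFCE along the window and max-statistic
    correction across states and time.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    tfce_params = tfce_params or TfceParams()
    X1 = _as_curve_stack(group1)
    X2 = _as_curve_stack(group2)
    n1, K, W = X1.shape
    n2 = X2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    if X2.shape[1:] != (K, W):
        raise ValueError("group curve shapes differ")
    sign = {"greater": 1.0, "less": -1.0}[direction]

    X = np.concatenate([X1, X2]).reshape(n1 + n2, K * W)
    rng = np.random.default_rng(seed)
    G, n_eff = _group_label_perms(n1 + n2, n1, nperm, rng)
    t = sign * _two_sample_t(X, G, n1, n2)  # (P+1, K*W)
    P1 = t.shape[0]
    enhanced = tfce1d_batch(t.reshape(P1 * K, W), tfce_params).reshape(P1, K, W)
    p = _fwe_p(enhanced, n_eff)
    return PermResult(
        observed=t[0].reshape(K, W),
        enhanced=enhanced[0],
        p_fwe=p,
        nperm=(n_eff - 1) if n_eff is not None else nperm,
        scheme=scheme + (" (exhaustive)" if n_eff is not None else ""),
        contrast=f"group1 {'>' if sign > 0 else '<'} group2",
    )


# ---------------------------------------------------------------------------
# repeated-measures frequency ANOVA
# ---------------------------------------------------------------------------

def _contrast_scores(curves: np.ndarray, assign: np.ndarray, weights: np.ndarray):
    """Weighted within-block combinations under permuted frequency labels.

    curves : (n_blocks, L, K, W); assign : (P, n_blocks, L) permuted level
    indices; weights : (L,).  Returns (P, n_blocks, K, W).
    """
    P, n_blocks, L = assign.shape
    wperm = np.zeros((P, n_blocks, L))
    p_ix = np.repeat(np.arange(P), n_blocks * L)
    b_ix = np.tile(np.repeat(np.arange(n_blocks), L), P)
    wperm[p_ix, b_ix, assign.ravel()] = np.tile(weights, P * n_blocks)
    return np.einsum("pbl,blkw->pbkw", wperm, curves)


def _one_sample_t(scores: np.ndarray) -> np.ndarray:
    """t across the block axis of (P, n_blocks, K, W)."""
    n = scores.shape[1]
    m = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    return m / np.sqrt(np.maximum(sd**2 / n, VAR_FLOOR))


def rm_anova_frequency(
    curves: np.ndarray,
    contrasts=THETA_CONTRASTS,
    tfce_params: TfceParams | None = None,
    nperm: int = 1000,
    seed: int = 0,
) -> dict:
    """Within-subject frequency ANOVA by block-aware permutation.

    Parameters
    ----------
    curves : (n_sessions, 3, K, W) ndarray
        One evoked curve per frequency level (columns ordered 5, 10, 20 Hz)
        for every session; each session is an exchangeability block.
    contrasts : sequence of ContrastSpec
        Post hoc directional contrasts.

    Returns
    -------
    dict with key ``"F"`` (omnibus frequency effect, a Hotelling-style
    statistic over two orthonormal within-subject contrasts, always assessed
    by permutation) and one key per contrast label (one-sided t).
    """
    tfce_params = tfce_params or TfceParams()
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 4 or curves.shape[1] != 3:
        raise ValueError("curves must be (n_sessions, 3 frequencies, K, W)")
    n_sess, L, K, W = curves.shape
    if n_sess < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng(seed)

    level_perms = np.array(list(itertools.permutations(range(L))))
    assign = np.empty((nperm + 1, n_sess, L), dtype=int)
    assign[0] = np.arange(L)
    assign[1:] = level_perms[rng.integers(0, len(level_perms), size=(nperm, n_sess))]
    # whole-block swaps: permuting session order leaves every statistic
    # below invariant (sessions enter as exchangeable units), so the
    # within-block shuffles above realize the block-aware scheme.

    # omnibus: mean squared one-sample t over an orthonormal basis of the
    # frequency-contrast space.  (A full covariance-inverted Hotelling T2
    # explodes under permutation whenever the 2x2 contrast covariance is
    # near-singular — common for probability curves pinned at 0 or 1 — so
    # the diagonal combination is used; significance is by permutation
    # either way, which keeps the test exact.)
    b1 = np.array([2.0, -1.0, -1.0]) / np.sqrt(6.0)
    b2 = np.array([0.0, 1.0, -1.0]) / np.sqrt(2.0)
    t1 = _one_sample_t(_contrast_scores(curves, assign, b1))
    t2 = _one_sample_t(_contrast_scores(curves, assign, b2))
    T2 = 0.5 * (t1**2 + t2**2)
    P1 = nperm + 1
    F_enh = tfce1d_batch(T2.reshape(P1 * K, W), tfce_params).reshape(P1, K, W)
    results = {
        "F": PermResult(
            observed=T2[0],
            enhanced=F_enh[0],
            p_fwe=_fwe_p(F_enh),
            nperm=nperm,
            scheme="within-session frequency-label permutation",
            contrast="frequency omnibus",
        )
    }
    for spec in contrasts:
        if spec.steps is not None:
            t = np.minimum.reduce(
                [_one_sample_t(_contrast_scores(curves, assign, np.asarray(w)))
                 for w in spec.steps]
            )
        else:
            t = _one_sample_t(_contrast_scores(curves, assign, np.asarray(spec.weights)))
        if spec.sidedness == "less":
            t = -t
        enh = tfce1d_batch(t.reshape(P1 * K, W), tfce_params).reshape(P1, K, W)
        results[spec.label] = PermResult(
            observed=t[0],
            enhanced=enh[0],
            p_fwe=_fwe_p(enh),
            nperm=nperm,
            scheme="within-session frequency-label permutation",
            contrast=spec.label,
        )
    return results


# ---------------------------------------------------------------------------
# mixed-design group x frequency interaction
# ---------------------------------------------------------------------------

def mixed_anova_interaction(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    contrasts=THETA_CONTRASTS,
    tfce_params: TfceParams | None = None,
    nperm: int = 1000,
    seed: int = 0,
) -> dict:
    """Group-by-frequency interaction on evoked curves.

    Each subject (axis 0 of the (n_subjects, 3, K, W) inputs; frequency
    columns ordered 5, 10, 20 Hz) is reduced to its frequency-contrast
    curves; the interaction for a contrast is a between-group two-sample t
    on those curves, with group labels permuted across subjects.  The
    omnibus statistic is the larger of the two contrasts' squared t values.

    Returns a dict with ``"F"`` plus ``(label, "A>B")`` and ``(label,
    "B>A")`` post hoc results per contrast.
    """
    tfce_params = tfce_params or TfceParams()
    A = np.asarray(curves_a, dtype=float)
    B = np.asarray(curves_b, dtype=float)
    if A.ndim != 4 or B.ndim != 4 or A.shape[1] != 3 or B.shape[1] != 3:
        raise ValueError("curves must be (n_subjects, 3 frequencies, K, W)")
    nA, _, K, W = A.shape
    nB = B.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    G, n_eff = _group_label_perms(nA + nB, nA, nperm, rng)
    P1 = G.shape[0]
    scheme = "group-label permutation on contrast curves"
    nperm_eff = (n_eff - 1) if n_eff is not None else nperm

    results = {}
    t_sq = []
    for spec in contrasts:
        w = np.asarray(spec.weights)
        scores = np.concatenate(
            [np.einsum("l,nlkw->nkw", w, A), np.einsum("l,nlkw->nkw", w, B)]
        ).reshape(nA + nB, K * W)
        t = _two_sample_t(scores, G, nA, nB)  # (P1, K*W)
        t_sq.append(t**2)
        for direction, tt in (("A>B", t), ("B>A", -t)):
            enh = tfce1d_batch(tt.reshape(P1 * K, W), tfce_params).reshape(P1, K, W)
            results[(spec.label, direction)] = PermResult(
                observed=tt[0].reshape(K, W),
                enhanced=enh[0],
                p_fwe=_fwe_p(enh, n_eff),
                nperm=nperm_eff,
                scheme=scheme,
                contrast=f"{spec.label} x group ({direction})",
            )
    Fstat = np.maximum.reduce(t_sq)
    enh = tfce1d_batch(Fstat.reshape(P1 * K, W), tfce_params).reshape(P1, K, W)
    results["F"] = PermResult(
        observed=Fstat[0].reshape(K, W),
        enhanced=enh[0],
        p_fwe=_fwe_p(enh, n_eff),
        nperm=nperm_eff,
        scheme=scheme,
        contrast="interaction omnibus",
    )
    return results
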