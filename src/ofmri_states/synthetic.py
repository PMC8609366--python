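"""Synthetic ofMRI cohorts with planted, frequency-tuned dynamic states.

The generator emulates the study design this package analyzes: three groups
of mice (an opsin-negative control group and two opsin-expressing groups, one
wild-type and one transgenic), each run being 720 volumes at TR = 1 s with 10
photostimulation blocks of 10 s on / 50 s off after a 50 s baseline.

The generative model mirrors the assumptions of the downstream hidden Markov
analysis: a latent Markov chain over ``K_true`` states emits multivariate
Gaussian BOLD observations (one mean activation map and one covariance per
state).  Photostimulation engages specific states by multiplicatively boosting
the transition-matrix columns of those states in proportion to a hemodynamic
drive — the stimulus boxcar convolved with a gamma HRF — with a gain that
depends on state, stimulation frequency and group.  Control-group gains are
zero, so control runs are pure baseline dynamics.

Default planted structure (``K_true`` = 5):

====  =======================  =====================================
state role                     engagement (opsin-expressing groups)
====  =======================  =====================================
0, 1  baseline states          never driven
2     5 Hz-tuned evoked state  driven at every frequency but
                               preferentially at 5 Hz (wild-type);
                               driven without any preference in the
                               transgenic group (tuning lost)
3     10 Hz-tuned evoked       preferentially driven at 10 Hz
      state                    (wild-type); preferentially driven at
                               both 5 and 10 Hz in the transgenic
                               group
4     post-stimulation state   equally driven at every frequency,
                               with the drive delayed by the block
                               duration
====  =======================  =====================================

Evoked states respond at every stimulation frequency (so they survive
median aggregation across a subject's mixed-frequency runs, and the
active-vs-control group test sees them with all frequencies combined) but
are *preferentially* engaged at their tuned frequency — the comparative
structure the frequency contrasts must recover.  Controls have zero gain
everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hrf import convolve_boxcar, gamma_hrf
from .io import RoiTimeSeries, write_run
from .paradigm import StimulationParadigm

GROUPS = ("WT-mCherry", "WT-ChR2", "3xTgAD-ChR2")
FREQUENCIES = (5, 10, 20)

#: engagement gains of the default ground truth (dimensionless boost per
#: unit drive on the transition-matrix columns of the engaged states); sized
#: so that a tuned state's activation probability rises to roughly 0.4-0.7
#: during its preferred-frequency blocks, the magnitude seen in evoked
#: optogenetic state responses.  UNTUNED_GAIN is the partial engagement at
#: non-preferred frequencies (evoked states respond everywhere, just less).
TUNED_GAIN = 40.0
UNTUNED_GAIN = 12.0
POST_GAIN = 12.0


class GenerationError(RuntimeError):
    pass


@dataclass
class GroundTruthModel:
    """Parameters of the generative state model.

    ``engagement_gain[group][frequency]`` is a length-``K_true`` vector of
    non-negative gains; a gain g boosts the corresponding transition-matrix
    column by a factor ``1 + g * drive(t)`` (rows renormalized), where the
    drive is the boxcar convolved with the gamma HRF and peak-normalized.
    ``state_drive_delay_s`` shifts the drive per state (used to make the
    post-stimulation state engage after block offset).
    """

    n_regions: int
    K_true: int
    state_means: np.ndarray  # (K, R)
    state_covs: np.ndarray  # (K, R, R)
    baseline_transition: np.ndarray  # (K, K) row-stochastic
    engagement_gain: dict  # group -> {freq: (K,) array}
    hrf_mean_lag_s: float = 6.0
    hrf_dispersion_s: float = 3.0
    state_drive_delay_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.baseline_transition, dtype=float)
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-10):
            raise GenerationError("baseline transition rows must sum to 1")
        if np.any(A < 0):
            raise GenerationError("baseline transition must be non-negative")
        for g, per_freq in self.engagement_gain.items():
            for f, vec in per_freq.items():
                v = np.asarray(vec, dtype=float)
                if v.shape != (self.K_true,) or np.any(~np.isfinite(v)) or np.any(v < 0):
                    raise GenerationError(
                        f"gain vector for ({g}, {f} Hz) must be a finite "
                        f"non-negative length-{self.K_true} vector"
                    )
        if self.state_drive_delay_s is None:
            self.state_drive_delay_s = np.zeros(self.K_true)

    def gain_vector(self, group: str, frequency: int) -> np.ndarray:
        per_freq = self.engagement_gain.get(group, {})
        vec = per_freq.get(int(frequency))
        if vec is None:
            return np.zeros(self.K_true)
        return np.asarray(vec, dtype=float)

    def cholesky_factors(self) -> np.ndarray:
        """Cholesky factor of each state covariance; raises naming the
        offending state if one is not positive definite."""
        chols = np.empty_like(self.state_covs)
        for k in range(self.K_true):
            try:
                chols[k] = np.linalg.cholesky(self.state_covs[k])
            except np.linalg.LinAlgError as exc:
                raise GenerationError(
                    f"state {k} covariance is not positive definite"
                ) from exc
        return chols

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the baseline chain."""
        vals, vecs = np.linalg.eig(self.baseline_transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def default_ground_truth(n_regions: int = 90, construction_seed: int = 1234) -> GroundTruthModel:
    """The default planted state model (see module docstring).

    State means are unit-scale region patterns; covariances are
    diagonal-plus-low-rank (diag in [0.8, 1.2] plus a rank-2 factor), which
    gives every state realistic functional-connectivity structure while
    guaranteeing positive definiteness.  The construction is deterministic
    for a given ``construction_seed``; run-level noise is seeded separately
    at simulation time.
    """
    K = 5
    rng = np.random.default_rng(construction_seed)
    means = rng.normal(0.0, 1.0, size=(K, n_regions))
    covs = np.empty((K, n_regions, n_regions))
    for k in range(K):
        d = rng.uniform(0.8, 1.2, size=n_regions)
        W = rng.normal(0.0, 0.25, size=(n_regions, 2))
        covs[k] = np.diag(d) + W @ W.T

    # sticky baseline chain: baseline states common, evoked states rare
    A = np.full((K, K), 0.0)
    for i in range(K):
        A[i] = [0.03, 0.03, 0.02 / 3, 0.02 / 3, 0.02 / 3]
        A[i, i] = 0.0
        A[i, i] = 0.92 + (0.08 - A[i].sum())
    A /= A.sum(axis=1, keepdims=True)

    z = np.zeros(K)

    def g(**kw):
        v = z.copy()
        for k, val in kw.items():
            v[int(k[1:])] = val
        return v

    gains = {
        "WT-mCherry": {5: z, 10: z, 20: z},
        "WT-ChR2": {
            5: g(s2=TUNED_GAIN, s3=UNTUNED_GAIN, s4=POST_GAIN),
            10: g(s2=UNTUNED_GAIN, s3=TUNED_GAIN, s4=POST_GAIN),
            20: g(s2=UNTUNED_GAIN, s3=UNTUNED_GAIN, s4=POST_GAIN),
        },
        "3xTgAD-ChR2": {
            5: g(s2=UNTUNED_GAIN, s3=TUNED_GAIN, s4=POST_GAIN),
            10: g(s2=UNTUNED_GAIN, s3=TUNED_GAIN, s4=POST_GAIN),
            20: g(s2=UNTUNED_GAIN, s3=UNTUNED_GAIN, s4=POST_GAIN),
        },
    }
    delays = np.zeros(K)
    delays[4] = 10.0  # post-stimulation state: drive starts at block offset
    return GroundTruthModel(
        n_regions=n_regions,
        K_true=K,
        state_means=means,
        state_covs=covs,
        baseline_transition=A,
        engagement_gain=gains,
        state_drive_delay_s=delays,
    )


def region_labels(n_regions: int) -> list[str]:
    return [f"R{i + 1:03d}" for i in range(n_regions)]


def _state_drives(gt: GroundTruthModel, paradigm: StimulationParadigm) -> np.ndarray:
    """Per-state hemodynamic drive, (K, n_volumes), peak-normalized."""
    box = paradigm.boxcar()
    kernel = gamma_hrf(paradigm.tr_s, gt.hrf_mean_lag_s, gt.hrf_dispersion_s)
    drive = convolve_boxcar(box, kernel)
    if drive.max() > 0:
        drive = drive / drive.max()
    K = gt.K_true
    drives = np.empty((K, paradigm.n_volumes))
    for k in range(K):
        shift = int(round(gt.state_drive_delay_s[k] / paradigm.tr_s))
        if shift == 0:
            drives[k] = drive
        else:
            drives[k] = np.concatenate([np.zeros(shift), drive[: paradigm.n_volumes - shift]])
    return drives


def simulate_run(
    gt: GroundTruthModel,
    paradigm: StimulationParadigm,
    group: str,
    frequency: int,
    seed,
    noise_scale: float = 1.0,
    meta: dict | None = None,
) -> tuple[RoiTimeSeries, np.ndarray, np.ndarray]:
    """Simulate one run: (time series, latent state path, latent gamma).

    The latent path is drawn from the drive-modulated Markov chain; the
    latent gamma is its one-hot encoding (rows sum to 1 exactly).  Emission
    at time t is the mean of the active state plus zero-mean Gaussian noise
    with that state's covariance, scaled by ``noise_scale``.
    """
    if int(frequency) not in FREQUENCIES:
        raise ValueError(f"frequency must be one of {FREQUENCIES}, got {frequency}")
    rng = np.random.default_rng(seed)
    K, R, T = gt.K_true, gt.n_regions, paradigm.n_volumes

    gains = gt.gain_vector(group, frequency)
    drives = _state_drives(gt, paradigm)  # (K, T)
    # column boost per time point: factor[t, k] multiplies the *incoming*
    # transitions of column k.  The diagonal keeps its baseline value so a
    # driven state is entered more often but not made absorbing — co-driven
    # states then show overlapping responses within a block instead of
    # winner-take-all occupancy.
    factor = 1.0 + gains[None, :] * drives.T  # (T, K)
    At = gt.baseline_transition[None, :, :] * factor[:, None, :]
    diag = np.arange(K)
    At[:, diag, diag] = gt.baseline_transition[diag, diag]
    At /= At.sum(axis=2, keepdims=True)
    Acum = np.cumsum(At, axis=2)

    path = np.empty(T, dtype=int)
    u = rng.random(T)
    pi0 = np.cumsum(gt.stationary_distribution())
    path[0] = int(np.searchsorted(pi0, u[0], side="right"))
    for t in range(1, T):
        path[t] = int(np.searchsorted(Acum[t, path[t - 1]], u[t], side="right"))
    path = np.minimum(path, K - 1)

    gamma = np.zeros((T, K))
    gamma[np.arange(T), path] = 1.0

    X = gt.state_means[path].copy()
    if noise_scale != 0.0:
        chols = gt.cholesky_factors()
        eps = rng.standard_normal((T, R))
        for k in range(K):
            sel = path == k
            if sel.any():
                X[sel] += noise_scale * eps[sel] @ chols[k].T
    ts = RoiTimeSeries(
        data=X,
        region_labels=region_labels(R),
        tr_s=paradigm.tr_s,
        meta=dict(meta or {}, group=group, freq_hz=int(frequency)),
    )
    return ts, path, gamma


def planted_means_in_standardized_units(
    gt: GroundTruthModel, latent_gammas, runs
) -> np.ndarray:
    """Planted state means expressed in the units the pipeline estimates.

    The analysis standardizes each run per region, so a recovered state mean
    is relative to the occupancy-weighted grand mean and scaled by the total
    per-region standard deviation.  This applies the same transformation to
    the generator's raw state means, giving the correct target for
    recovered-map comparisons.
    """
    latent = np.vstack(latent_gammas)
    pi = latent.mean(axis=0)
    mu_bar = pi @ gt.state_means
    raw = np.vstack([r.data for r in runs])
    sd = raw.std(axis=0)
    return (gt.state_means - mu_bar) / np.where(sd > 0, sd, 1.0)


def synthetic_connectome(
    n_regions: int,
    target_map: np.ndarray | None = None,
    density: float = 0.25,
    n_sources: int = 8,
    noise: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic directed tracer connectome (stand-in for a real tracer
    atlas), returning ``(C, w_true)``.

    ``C[i, j]`` is the non-negative projection magnitude from source j to
    target i, sparse at the given density.  When ``target_map`` is given,
    ``n_sources`` random columns are re-weighted so that the map is (noisy)
    linear in the columns: ``target_map ~ C @ w_true + noise``; this plants a
    recoverable structure-function relation for the ridge-mapping stage.
    """
    rng = np.random.default_rng(seed)
    C = rng.lognormal(mean=0.0, sigma=1.0, size=(n_regions, n_regions))
    C *= rng.random((n_regions, n_regions)) < density
    np.fill_diagonal(C, rng.lognormal(0.0, 1.0, n_regions))
    w = np.zeros(n_regions)
    if target_map is not None:
        m = np.asarray(target_map, dtype=float)
        m = (m - m.min()) / max(m.std(), 1e-12)  # non-negative, unit scale
        src = rng.choice(n_regions, size=n_sources, replace=False)
        w[src] = rng.uniform(0.5, 1.5, n_sources)
        for j in src:
            C[:, j] = noise * C[:, j] + w[j] * m
    return C, w


@dataclass
class CohortSpec:
    """Cohort layout.

    ``groups`` maps each group label to the number of subjects imaged in
    each session (a list with one entry per session); every session of a
    participating subject holds one run per stimulation frequency.

    The default reproduces the study bookkeeping: 9 control subjects with a
    single session, 10 wild-type active subjects of whom 8 returned for the
    second session, and 12 transgenic active subjects with two full
    sessions — 27 + 54 + 72 = 153 runs of 720 volumes (110,160 total time
    points).
    """

    groups: dict = field(
        default_factory=lambda: {
            "WT-mCherry": [9],
            "WT-ChR2": [10, 8],
            "3xTgAD-ChR2": [12, 12],
        }
    )
    frequencies: tuple = FREQUENCIES
    paradigm: StimulationParadigm = field(default_factory=StimulationParadigm)

    def manifest(self) -> pd.DataFrame:
        rows = []
        sub_idx = 0
        for group, per_session in self.groups.items():
            per_session = list(per_session)
            for i in range(max(per_session)):
                sub_idx += 1
                sid = f"sub-{sub_idx:03d}"
                run_idx = 0
                for sess, n_in_sess in enumerate(per_session, start=1):
                    if i >= n_in_sess:
                        continue
                    for f in self.frequencies:
                        run_idx += 1
                        rows.append(
                            dict(
                                subject_id=sid,
                                group=group,
                                session=sess,
                                run=run_idx,
                                freq_hz=int(f),
                                path=f"{sid}_ses-{sess}_run-{run_idx}_freq-{f}.tsv",
                            )
                        )
        return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortSpec | None = None,
    gt: GroundTruthModel | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    noise_scale: float = 1.0,
):
    """Simulate a whole cohort.

    Returns ``(manifest, runs, truth)`` where ``runs`` is the list of
    :class:`RoiTimeSeries` in manifest order and ``truth`` maps each manifest
    row index to its latent path and gamma plus the ground-truth model.  When
    ``out_dir`` is given, run tables, the manifest, latent paths and a
    ground-truth JSON are written there (refusing to clobber existing files
    unless ``overwrite``).  Outputs are deterministic given (config, gt, seed).
    """
    config = config or CohortSpec()
    gt = gt if gt is not None else default_ground_truth()
    manifest = config.manifest()
    seeds = np.random.SeedSequence(seed).spawn(len(manifest))

    runs, paths, gammas = [], [], []
    for i, row in manifest.iterrows():
        ts, path, gamma = simulate_run(
            gt,
            config.paradigm,
            row.group,
            row.freq_hz,
            seeds[i],
            noise_scale=noise_scale,
            meta=dict(subject_id=row.subject_id, session=int(row.session), run=int(row.run)),
        )
        runs.append(ts)
        paths.append(path)
        gammas.append(gamma)

    truth = dict(model=gt, paths=paths, gammas=gammas)
    if out_dir is not None:
        _write_cohort(Path(out_dir), config, gt, manifest, runs, paths, seed, overwrite)
    return manifest, runs, truth


def _write_cohort(out_dir, config, gt, manifest, runs, paths, seed, overwrite):
    out_dir.mkdir(parents=True, exist_ok=True)
    targets = [out_dir / p for p in manifest.path] + [out_dir / "manifest.tsv"]
    clashes = [str(p) for p in targets if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite {len(clashes)} existing file(s), e.g. {clashes[0]}; "
            "pass overwrite=True"
        )
    for ts, rel in zip(runs, manifest.path):
        write_run(ts, out_dir / rel)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)

    gt_dir = out_dir / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    path_files = []
    for i, p in enumerate(paths):
        rel = f"ground_truth/latent_path_{i:03d}.tsv"
        np.savetxt(out_dir / rel, p[:, None], fmt="%d", delimiter="\t", header="state", comments="")
        path_files.append(rel)
    np.savetxt(
        gt_dir / "state_means.tsv",
        gt.state_means,
        delimiter="\t",
        header="\t".join(region_labels(gt.n_regions)),
        comments="",
    )
    np.savetxt(
        gt_dir / "state_covs_stacked.tsv",
        gt.state_covs.reshape(gt.K_true * gt.n_regions, gt.n_regions),
        delimiter="\t",
    )
    meta = dict(
        seed=int(seed),
        K_true=int(gt.K_true),
        n_regions=int(gt.n_regions),
        hrf=dict(mean_lag_s=gt.hrf_mean_lag_s, dispersion_s=gt.hrf_dispersion_s),
        state_drive_delay_s=list(map(float, gt.state_drive_delay_s)),
        engagement_gain={
            g: {str(f): list(map(float, v)) for f, v in per.items()}
            for g, per in gt.engagement_gain.items()
        },
        paradigm=config.paradigm.to_dict(),
        latent_path_files=path_files,
        state_means_file="ground_truth/state_means.tsv",
        state_covs_file="ground_truth/state_covs_stacked.tsv",
    )
    (gt_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2))
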