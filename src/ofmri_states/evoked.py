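"""Time-locked evoked state responses.

For each stimulation block, the window of interest spans the block duration
plus an equal post-stimulation span (by default 10 s on + 10 s off = 20
samples at TR 1 s), anchored at stimulation onset.  The run-level evoked
response of a state is the elementwise *median* of its activation probability
across the blocks (robust to outlier blocks); the subject-level response is
the median across the subject's selected runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import StimulationParadigm

logger = logging.getLogger(__name__)


@dataclass
class BlockSeries:
    """Per-block windows of state activation probability, (K, n_blocks, W)."""

    windows: np.ndarray
    on_samples: int
    block_order: np.ndarray = None  # original block indices retained

    def __post_init__(self):
        if self.block_order is None:
            self.block_order = np.arange(self.windows.shape[1])

    @property
    def n_blocks(self) -> int:
        return self.windows.shape[1]


@dataclass
class EvokedResponse:
    """K x W activation-probability curves, run- or subject-level."""

    curves: np.ndarray  # (K, W)
    level: str  # "run" | "subject"
    on_samples: int
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.curves.shape[0]

    @property
    def window(self) -> int:
        return self.curves.shape[1]


def block_windows(
    gamma_run: np.ndarray,
    paradigm: StimulationParadigm,
    post_samples: int | None = None,
) -> BlockSeries:
    """Extract the per-block windows of a run's gamma.

    The window for a block starts at its onset sample and spans
    ``on_samples + post_samples`` samples (post defaults to on, the 10 on /
    10 off convention).  Blocks truncated by the end of the run are dropped
    with a warning; zero usable blocks is an error.
    """
    gamma_run = np.asarray(gamma_run, dtype=float)
    if gamma_run.shape[0] != paradigm.n_volumes:
        raise ValueError(
            f"gamma has {gamma_run.shape[0]} rows, paradigm expects "
            f"{paradigm.n_volumes} volumes"
        )
    on = paradigm.on_samples
    post = on if post_samples is None else int(post_samples)
    W = on + post
    wins, kept = [], []
    for b, onset in enumerate(paradigm.block_onsets()):
        if onset + W > paradigm.n_volumes:
            msg = f"block {b} window [{onset}, {onset + W}) exceeds run length; dropped"
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            continue
        wins.append(gamma_run[onset : onset + W].T)  # (K, W)
        kept.append(b)
    if not wins:
        raise ValueError("no usable stimulation blocks in this run")
    return BlockSeries(
        windows=np.stack(wins, axis=1), on_samples=on, block_order=np.array(kept)
    )


def run_evoked(blocks: BlockSeries, meta: dict | None = None) -> EvokedResponse:
    """Elementwise median across blocks (midpoint convention for even
    counts)."""
    curves = np.median(blocks.windows, axis=1)
    return EvokedResponse(
        curves=curves, level="run", on_samples=blocks.on_samples, meta=dict(meta or {})
    )


def subject_evoked(
    manifest: pd.DataFrame,
    run_responses: list[EvokedResponse],
    where=None,
) -> list[EvokedResponse]:
    """Aggregate run-level responses to one response per subject.

    ``where`` is an optional boolean predicate over manifest rows (callable
    on the row, or a boolean mask) selecting which runs enter each subject's
    median.  Subjects with no selected runs are dropped with a warning.
    """
    if len(run_responses) != len(manifest):
        raise ValueError("one run response per manifest row is required")
    if where is None:
        mask = np.ones(len(manifest), dtype=bool)
    elif callable(where):
        mask = manifest.apply(where, axis=1).to_numpy(dtype=bool)
    else:
        mask = np.asarray(where, dtype=bool)

    out = []
    for sid, rows in manifest.groupby("subject_id", sort=False):
        sel = [i for i in rows.index if mask[manifest.index.get_loc(i)]]
        if not sel:
            msg = f"subject {sid} has no runs after filtering; dropped"
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            continue
        stack = np.stack([run_responses[manifest.index.get_loc(i)].curves for i in sel])
        out.append(
            EvokedResponse(
                curves=np.median(stack, axis=0),
                level="subject",
                on_samples=run_responses[manifest.index.get_loc(sel[0])].on_samples,
                meta=dict(
                    subject_id=sid,
                    group=rows.loc[sel[0], "group"],
                    n_runs=len(sel),
                ),
            )
        )
    return out


def single_block_evoked(
    blocks_per_run: list[BlockSeries], block_index: int
) -> list[EvokedResponse]:
    """Run-level responses restricted to one block (for long-scale
    profiling)."""
    out = []
    for bs in blocks_per_run:
        pos = np.where(bs.block_order == block_index)[0]
        if pos.size == 0:
            raise ValueError(f"block {block_index} not present in run")
        out.append(
            EvokedResponse(
                curves=bs.windows[:, pos[0], :],
                level="run",
                on_samples=bs.on_samples,
            )
        )
    return out


def block_significance_profile(
    manifest1,
    blocks1: list[BlockSeries],
    manifest2,
    blocks2: list[BlockSeries],
    n_blocks: int,
    nperm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    tfce_params=None,
):
    """Per-block group-difference significance: for each block b, apply the
    standard FWE group test to the block-b windows only.

    Returns ``(profile, p_curves)``: a (K, n_blocks) boolean array marking
    states significant at any window sample within each block, and the list
    of per-block FWE p-curve arrays (K, W).
    """
    from .permstats import group_difference_test  # local import, no cycle

    profiles, p_all = [], []
    for b in range(n_blocks):
        runs1 = single_block_evoked(blocks1, b)
        runs2 = single_block_evoked(blocks2, b)
        subj1 = subject_evoked(manifest1, runs1)
        subj2 = subject_evoked(manifest2, runs2)
        res = group_difference_test(
            subj1, subj2, nperm=nperm, seed=seed + b, tfce_params=tfce_params
        )
        p_all.append(res.p_fwe)
        profiles.append((res.p_fwe <= alpha).any(axis=1))
    return np.stack(profiles, axis=1), p_all
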