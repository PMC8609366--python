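"""Reading, writing, standardization and concatenation of ROI time series.

Run files are tab-separated: a header row of region labels, one row per
volume, no index column.  The manifest is tab-separated with columns
``subject_id, group, session, run, freq_hz, path`` (paths relative to the
manifest's directory).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["subject_id", "group", "session", "run", "freq_hz", "path"]


@dataclass
class RoiTimeSeries:
    """One run's time x region BOLD matrix with acquisition metadata."""

    data: np.ndarray
    region_labels: list[str]
    tr_s: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (time x regions)")
        if self.data.shape[1] != len(self.region_labels):
            raise ValueError(
                f"{self.data.shape[1]} data columns vs "
                f"{len(self.region_labels)} region labels"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def write_run(ts: RoiTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_run(path: str | Path, tr_s: float = 1.0, meta: dict | None = None) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        data=df.to_numpy(dtype=float),
        region_labels=list(df.columns),
        tr_s=tr_s,
        meta=dict(meta or {}, path=str(path)),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    return df


def load_cohort(manifest_path: str | Path, tr_s: float = 1.0):
    """Read a manifest and all run files it references."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    runs = [
        read_run(
            manifest_path.parent / row.path,
            tr_s=tr_s,
            meta=dict(
                subject_id=row.subject_id,
                group=row.group,
                session=int(row.session),
                run=int(row.run),
                freq_hz=int(row.freq_hz),
            ),
        )
        for row in manifest.itertuples()
    ]
    return manifest, runs


def standardize_run(run: RoiTimeSeries) -> RoiTimeSeries:
    """Z-score each region within the run (population variance).

    Constant regions become all-zero columns with a logged warning;
    non-finite input is a hard error naming the run and region.
    """
    X = run.data
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 time points")
    if not np.all(np.isfinite(X)):
        bad = np.where(~np.isfinite(X).all(axis=0))[0]
        labels = [run.region_labels[i] for i in bad[:5]]
        raise ValueError(
            f"non-finite values in run {run.meta.get('path', run.meta)} "
            f"regions {labels}"
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (ddof=0) normalization
    const = sd == 0
    if const.any():
        labels = [run.region_labels[i] for i in np.where(const)[0]]
        msg = f"constant region(s) {labels} set to zero in run {run.meta.get('path', '')}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    return RoiTimeSeries(Z, run.region_labels, run.tr_s, dict(run.meta))


@dataclass
class ConcatData:
    """Temporally concatenated runs plus the row range of each run."""

    data: np.ndarray
    row_ranges: list[tuple[int, int]]
    region_labels: list[str]
    manifest: pd.DataFrame | None = None

    @property
    def lengths(self) -> list[int]:
        return [b - a for a, b in self.row_ranges]

    def split(self, X: np.ndarray | None = None) -> list[np.ndarray]:
        """Split a total_time-long array (default: the data) back into runs."""
        X = self.data if X is None else X
        return [X[a:b] for a, b in self.row_ranges]


def concatenate(manifest: pd.DataFrame | None, runs: list[RoiTimeSeries]) -> ConcatData:
    """Stack runs in manifest order after checking region headers match."""
    if not runs:
        raise ValueError("no runs to concatenate")
    labels = runs[0].region_labels
    for i, r in enumerate(runs[1:], start=1):
        if r.region_labels != labels:
            diff = sorted(set(r.region_labels) ^ set(labels))
            raise ValueError(
                f"run {i} region header mismatch; differing labels: {diff[:10]}"
            )
    ranges, start = [], 0
    for r in runs:
        ranges.append((start, start + r.n_volumes))
        start += r.n_volumes
    data = np.vstack([r.data for r in runs])
    return ConcatData(data=data, row_ranges=ranges, region_labels=labels, manifest=manifest)
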