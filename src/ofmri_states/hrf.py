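"""Hemodynamic response kernel.

A single-gamma HRF: the BOLD response to a brief neural event is modeled as a
gamma probability density with a mean lag of ~6 s and a dispersion (standard
deviation) of ~3 s, truncated at 32 s.  The kernel is peak-normalized so that
convolving a boxcar yields a drive on an interpretable 0..~on-duration scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def gamma_hrf(
    tr_s: float = 1.0,
    mean_lag_s: float = 6.0,
    dispersion_s: float = 3.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Sample a peak-normalized gamma-density HRF kernel at the TR.

    The gamma density is parameterized by its mean ``mean_lag_s`` and
    standard deviation ``dispersion_s``: shape = (mean/sd)^2 and
    scale = sd^2/mean.  Support starts at t = 0 (causal kernel).
    """
    if min(tr_s, mean_lag_s, dispersion_s, length_s) <= 0:
        raise ValueError("all HRF parameters must be positive")
    shape = (mean_lag_s / dispersion_s) ** 2
    scale = dispersion_s**2 / mean_lag_s
    t = np.arange(0.0, length_s, tr_s)
    k = stats.gamma.pdf(t, a=shape, scale=scale)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate HRF kernel (all-zero)")
    return k / peak


def convolve_boxcar(boxcar: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of a stimulus vector with an HRF kernel,
    truncated to the stimulus length."""
    boxcar = np.asarray(boxcar, dtype=float)
    return np.convolve(boxcar, kernel)[: boxcar.size]
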