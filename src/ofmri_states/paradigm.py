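"""Block-design photostimulation paradigm.

The experimental protocol this package targets delivers light pulses in a
fixed block design: an initial rest baseline, then ``n_blocks`` stimulation
blocks of ``on_s`` seconds each followed by ``off_s`` seconds of rest, and a
final rest tail, sampled at one fMRI volume per ``tr_s`` seconds.  Within a
block, light is pulsed at ``pulse_freq_hz`` with pulses of ``pulse_width_ms``;
at the volume level (the resolution of every analysis here) a block is simply
a contiguous ON segment of the boxcar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


class InvalidParadigmError(ValueError):
    """Raised when a stimulation paradigm is internally inconsistent."""


def duty_cycle(pulse_width_ms: float, pulse_freq_hz: float) -> float:
    """Light duty cycle, in percent, of a pulse train.

    Parameters
    ----------
    pulse_width_ms : float
        Width of a single light pulse in milliseconds. Must be positive.
    pulse_freq_hz : float
        Pulse repetition frequency in Hz. Must be positive.

    Returns
    -------
    float
        ``pulse_width_ms / 1000 * pulse_freq_hz * 100`` — the percentage of
        time the light is on during a stimulation block.  10-ms pulses at
        20, 10 and 5 Hz give 20, 10 and 5 %.
    """
    if pulse_width_ms <= 0 or pulse_freq_hz <= 0:
        raise InvalidParadigmError(
            f"pulse width and frequency must be positive, got "
            f"{pulse_width_ms} ms at {pulse_freq_hz} Hz"
        )
    pct = pulse_width_ms / 1000.0 * pulse_freq_hz * 100.0
    if pct > 100.0:
        raise InvalidParadigmError(
            f"duty cycle {pct:.1f}% exceeds 100% "
            f"({pulse_width_ms} ms pulses at {pulse_freq_hz} Hz)"
        )
    return pct


@dataclass
class StimulationParadigm:
    """Timing of a block-design photostimulation run.

    Defaults reproduce the study design: 50 s baseline, 10 blocks of
    10 s on / 50 s off, 60 s tail, TR = 1 s, 720 volumes.  The scheduled
    duration (50 + 10x60 + 60 = 710 s) is shorter than the acquisition;
    the surplus volumes are treated as extra tail rest, since every
    analysis locks to block onsets and the placement of spare rest is
    inert.
    """

    baseline_s: float = 50.0
    n_blocks: int = 10
    on_s: float = 10.0
    off_s: float = 50.0
    tail_s: float = 60.0
    tr_s: float = 1.0
    n_volumes: int = 720
    pulse_freq_hz: float = 20.0
    pulse_width_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise InvalidParadigmError(f"tr_s must be positive, got {self.tr_s}")
        if self.n_volumes <= 0:
            raise InvalidParadigmError(
                f"n_volumes must be positive, got {self.n_volumes}"
            )
        if min(self.baseline_s, self.on_s, self.off_s, self.tail_s) < 0:
            raise InvalidParadigmError("durations must be non-negative")
        if self.n_blocks < 0:
            raise InvalidParadigmError(f"n_blocks must be >= 0, got {self.n_blocks}")
        # validates the pulse train as a side effect
        duty_cycle(self.pulse_width_ms, self.pulse_freq_hz)

    @property
    def on_samples(self) -> int:
        """Number of volumes in one ON segment."""
        return int(round(self.on_s / self.tr_s))

    @property
    def duty_cycle_pct(self) -> float:
        return duty_cycle(self.pulse_width_ms, self.pulse_freq_hz)

    def block_onsets(self) -> np.ndarray:
        """Sample index of the first ON volume of each block."""
        onsets_s = self.baseline_s + np.arange(self.n_blocks) * (self.on_s + self.off_s)
        return np.round(onsets_s / self.tr_s).astype(int)

    def boxcar(self) -> np.ndarray:
        """0/1 stimulus vector of length ``n_volumes``.

        Blocks extending past the end of the acquisition are truncated;
        unscheduled volumes are zero (rest).
        """
        box = np.zeros(self.n_volumes, dtype=float)
        w = self.on_samples
        for onset in self.block_onsets():
            if onset >= self.n_volumes:
                break
            box[onset : min(onset + w, self.n_volumes)] = 1.0
        return box

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationParadigm":
        return cls(**d)


def build_paradigm(config: StimulationParadigm | dict | None = None) -> np.ndarray:
    """Build the boxcar stimulus vector for a paradigm (defaults if None)."""
    if config is None:
        config = StimulationParadigm()
    elif isinstance(config, dict):
        config = StimulationParadigm.from_dict(config)
    return config.boxcar()
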