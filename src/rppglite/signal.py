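"""Uniformly sampled 1-D signals and the heart-rate frequency band.

The whole package works on plain ``Signal1D`` containers: a PPG waveform, a
predicted rPPG waveform, or the spatially pooled temporal trace of an
intermediate network layer — always a real, uniformly sampled sequence with
its sampling rate attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Signal1D", "BandpassSpec", "HR_BAND", "mean_center"]


@dataclass(frozen=True)
class Signal1D:
    """A real, uniformly sampled time series.

    Parameters
    ----------
    values : ndarray, shape (N,)
        Sample values in arbitrary units. Must be finite and have N >= 2.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("Signal1D needs a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("Signal1D values must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate fs must be > 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class BandpassSpec:
    """A passband [f_lo, f_hi] in Hz; 0 < f_lo < f_hi."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")

    def validate_for(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz is at or above Nyquist ({fs / 2} Hz)"
            )

    @property
    def lo_bpm(self) -> float:
        return self.f_lo * 60.0

    @property
    def hi_bpm(self) -> float:
        return self.f_hi * 60.0


#: The heart-rate band 40–180 bpm used throughout: loss bandpass, HR
#: estimation, and spectral visualization.
HR_BAND = BandpassSpec(40.0 / 60.0, 180.0 / 60.0)


def mean_center(s: Signal1D) -> Signal1D:
    """Subtract the mean, keeping length and sampling rate.

    The spectral losses operate on fluctuations only, so the mean is removed
    before any transform.
    """
    return Signal1D(s.values - s.values.mean(), s.fs)
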