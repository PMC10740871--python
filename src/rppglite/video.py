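"""Video clip container: a 3xTxHxW intensity tensor with its frame rate."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .signal import Signal1D

__all__ = ["VideoClip"]


@dataclass
class VideoClip:
    """A color video clip with an optional paired reference PPG label.

    Attributes
    ----------
    frames : ndarray, shape (3, T, H, W)
        Channel-first RGB intensities, nominally in [0, 1].
    fs : float
        Frame rate in Hz.
    label : Signal1D, optional
        Ground-truth PPG resampled to the frame rate (length T).
    """

    frames: np.ndarray
    fs: float
    label: Optional[Signal1D] = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 4 or frames.shape[0] != 3:
            raise ValueError(f"frames must be (3, T, H, W), got {frames.shape}")
        if not (self.fs > 0):
            raise ValueError("frame rate must be > 0")
        if self.label is not None and len(self.label) != frames.shape[1]:
            raise ValueError(
                f"label length {len(self.label)} != number of frames {frames.shape[1]}"
            )
        self.frames = frames

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.frames.shape)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs
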