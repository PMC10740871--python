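"""Inspection views of the trained network.

Three views expose what the spatiotemporal layers learn: spatial activation
snapshots tiled channel-by-channel into a square grid; temporal traces (the
spatial mean of each channel over time); and their magnitude spectra
restricted to the heart-rate band, where the pulse periodicity of deeper
layers becomes conspicuous. The learned stem kernels, which see raw RGB,
render directly as small color patches.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np

from .network import TapOutput
from .signal import BandpassSpec, HR_BAND, Signal1D

__all__ = [
    "ActivationSnapshot",
    "SpectralTrace",
    "tile_grid",
    "temporal_traces",
    "spectral_traces",
    "filter_grid",
    "save_image",
]


@dataclass(frozen=True)
class ActivationSnapshot:
    """One layer's activation at a single time index: (C, H_l, W_l)."""

    layer_name: str
    tensor: np.ndarray

    def __post_init__(self) -> None:
        tensor = np.asarray(self.tensor, dtype=float)
        if tensor.ndim != 3 or tensor.shape[0] < 1:
            raise ValueError("snapshot tensor must be (C, H, W) with C >= 1")
        if not np.all(np.isfinite(tensor)):
            raise ValueError("snapshot contains non-finite values")
        object.__setattr__(self, "tensor", tensor)


@dataclass(frozen=True)
class SpectralTrace:
    """Per-channel magnitude spectra of one layer, on an in-band grid."""

    layer_name: str
    freqs_hz: np.ndarray          # (F,)
    magnitudes: np.ndarray        # (C, F), non-negative


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def tile_grid(snapshot: ActivationSnapshot) -> np.ndarray:
    """Tile per-channel maps into a ceil(sqrt(C))-square grid, row-major.

    Each channel is min-max normalized to [0, 1] before placement; unused
    cells are zero.
    """
    c, h, w = snapshot.tensor.shape
    side = ceil(sqrt(c))
    grid = np.zeros((side * h, side * w))
    for k in range(c):
        r, col = divmod(k, side)
        grid[r * h:(r + 1) * h, col * w:(col + 1) * w] = _minmax(snapshot.tensor[k])
    return grid


def temporal_traces(taps: list[TapOutput]) -> dict[str, list[Signal1D]]:
    """One Signal1D per channel per layer, at that layer's effective rate."""
    out: dict[str, list[Signal1D]] = {}
    for tap in taps:
        out[tap.layer_name] = [
            Signal1D(np.asarray(tap.pooled[ch], dtype=float), tap.fs_l)
            for ch in range(tap.pooled.shape[0])
        ]
    return out


def spectral_traces(
    traces: dict[str, list[Signal1D]],
    band: BandpassSpec = HR_BAND,
) -> dict[str, SpectralTrace]:
    """Magnitude spectra per channel, DC removed, grid limited to the band."""
    out: dict[str, SpectralTrace] = {}
    for name, channels in traces.items():
        n = len(channels[0])
        if n < 8:
            raise ValueError(f"trace of layer {name} too short ({n} < 8 samples)")
        fs = channels[0].fs
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        keep = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        mags = np.stack([
            np.abs(np.fft.rfft(ch.values - ch.values.mean()))[keep]
            for ch in channels
        ])
        out[name] = SpectralTrace(name, freqs[keep], mags)
    return out


def filter_grid(stem_weights: np.ndarray) -> np.ndarray:
    """Render stem kernels (C_out, 3, 1, 5, 5) as a row-major RGB patch grid.

    Each output channel's 3x5x5 kernel becomes one 5x5 RGB patch, min-max
    normalized per filter; returns an (side*5, side*5, 3) image with zeroed
    unused cells.
    """
    w = np.asarray(stem_weights, dtype=float)
    if w.ndim != 5 or w.shape[1] != 3:
        raise ValueError(
            f"expected stem weights (C_out, 3, 1, kh, kw) for RGB rendering, got {w.shape}"
        )
    c_out, _, _, kh, kw = w.shape
    side = ceil(sqrt(c_out))
    grid = np.zeros((side * kh, side * kw, 3))
    for k in range(c_out):
        patch = _minmax(w[k, :, 0])                 # (3, kh, kw) jointly normalized
        r, col = divmod(k, side)
        grid[r * kh:(r + 1) * kh, col * kw:(col + 1) * kw] = patch.transpose(1, 2, 0)
    return grid


def save_image(img: np.ndarray, path, cmap: str = "gray") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if img.ndim == 2:
        plt.imsave(path, img, cmap=cmap, vmin=0.0, vmax=1.0)
    else:
        plt.imsave(path, np.clip(img, 0, 1))
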