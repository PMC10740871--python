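"""Spectral deep supervision: auxiliary losses on intermediate-layer traces.

Each supervision tap yields a (C, T_l) spatially pooled activation matrix.
Its channel-mean trace is compared — by default with the negated maximum
cross-correlation loss, so minimizing maximizes band-limited correlation —
against the PPG label down-sampled to that depth's temporal length. Each
auxiliary term enters the total with weight 0.1 relative to the primary
waveform loss. The taps are pure reductions, so supervision adds zero
trainable parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import TAP_NAMES
from .losses import loss_value_with_grad
from .signal import BandpassSpec, HR_BAND, Signal1D

logger = logging.getLogger(__name__)

__all__ = [
    "SupervisionConfig",
    "downsample_label",
    "tap_trace",
    "composite_loss",
    "composite_loss_batch",
]


@dataclass(frozen=True)
class SupervisionConfig:
    """How the primary and auxiliary losses are composed.

    ``channel_mode`` selects how a multi-channel tap becomes a prediction:
    ``"mean"`` (default) averages channels into one consensus trace;
    ``"per_channel"`` averages the per-channel auxiliary losses instead.
    """

    primary_loss: str = "mse"
    aux_loss: str = "negmcc"
    aux_weight: float = 0.1
    tap_names: tuple[str, ...] = TAP_NAMES
    enabled: bool = True
    channel_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.aux_weight < 0:
            raise ValueError("aux_weight must be >= 0")
        if self.enabled and self.aux_weight > 0 and not self.tap_names:
            raise ValueError("deep supervision enabled but no tap names given")
        unknown = set(self.tap_names) - set(TAP_NAMES)
        if unknown:
            raise ValueError(f"unknown tap names {sorted(unknown)}; valid: {TAP_NAMES}")
        if self.channel_mode not in ("mean", "per_channel"):
            raise ValueError("channel_mode must be 'mean' or 'per_channel'")

    def to_dict(self) -> dict:
        return {
            "primary_loss": self.primary_loss,
            "aux_loss": self.aux_loss,
            "aux_weight": self.aux_weight,
            "tap_names": list(self.tap_names),
            "enabled": self.enabled,
            "channel_mode": self.channel_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SupervisionConfig":
        d = dict(d)
        if "tap_names" in d:
            d["tap_names"] = tuple(d["tap_names"])
        return cls(**d)


def downsample_label(ppg: Signal1D, target_t: int) -> Signal1D:
    """Down-sample a label to a layer's temporal length by linear interpolation.

    The new sampling rate is fs * target_t / N, so an in-band spectral peak
    stays at the same physical frequency.
    """
    n = len(ppg)
    if target_t < 2:
        raise ValueError("target_t must be >= 2")
    if target_t > n:
        raise ValueError(f"cannot down-sample length {n} to larger length {target_t}")
    if target_t == n:
        return ppg
    positions = np.arange(target_t) * (n / target_t)
    values = np.interp(positions, np.arange(n), ppg.values)
    return Signal1D(values, ppg.fs * target_t / n)


def tap_trace(tap) -> Signal1D:
    """Channel-mean temporal trace of a tap's pooled (C, T_l) matrix."""
    pooled = np.asarray(tap.pooled, dtype=float)
    if pooled.ndim != 2 or pooled.size == 0:
        raise ValueError("tap pooled matrix must be a nonempty (C, T_l) array")
    return Signal1D(pooled.mean(axis=0), tap.fs_l)


def _aux_term(
    pooled: np.ndarray,
    fs_l: float,
    label_ds: Signal1D,
    kind: str,
    band: BandpassSpec,
    channel_mode: str,
):
    """Auxiliary loss for one tap of one sample: (value, grad (C, T_l)) or None.

    Degenerate (zero-variance) traces are skipped: a constant activation has
    no defined direction under a correlation loss, which happens routinely in
    the first batches of training.
    """
    c, t_l = pooled.shape
    if channel_mode == "mean":
        trace = pooled.mean(axis=0)
        if np.std(trace) == 0.0:
            return None
        value, grad_trace = loss_value_with_grad(
            kind, label_ds, Signal1D(trace, fs_l), band
        )
        grad = np.broadcast_to(grad_trace / c, (c, t_l))
        return value, grad
    # per-channel: average of per-channel losses over non-degenerate channels
    values, grads, kept = [], np.zeros_like(pooled, dtype=float), 0
    for ch in range(c):
        if np.std(pooled[ch]) == 0.0:
            continue
        value, grad_ch = loss_value_with_grad(
            kind, label_ds, Signal1D(pooled[ch], fs_l), band
        )
        values.append(value)
        grads[ch] = grad_ch
        kept += 1
    if kept == 0:
        return None
    return float(np.mean(values)), grads / kept


def composite_loss_batch(
    rppg: np.ndarray,
    taps: dict[str, np.ndarray],
    labels: np.ndarray,
    fs: float,
    sup: SupervisionConfig,
    band: BandpassSpec = HR_BAND,
):
    """Total loss and gradients for a (N, T) batch.

    Returns
    -------
    total : float
        primary + aux_weight * sum of per-tap auxiliary means.
    breakdown : dict
        "primary", "aux/<tap>" per-tap batch means, and "aux_skipped" count.
    d_rppg : ndarray (N, T)
        Gradient of the total with respect to the predicted waveforms.
    tap_grads : dict name -> ndarray (N, C, T_l)
        Gradients with respect to the pooled tap activations.
    """
    n_batch, t = rppg.shape
    if labels.shape != rppg.shape:
        raise ValueError(f"labels shape {labels.shape} != rppg shape {rppg.shape}")

    primary_sum = 0.0
    d_rppg = np.zeros_like(rppg, dtype=float)
    for i in range(n_batch):
        value, grad = loss_value_with_grad(
            sup.primary_loss, Signal1D(labels[i], fs), Signal1D(rppg[i], fs), band
        )
        primary_sum += value
        d_rppg[i] = grad
    primary = primary_sum / n_batch
    d_rppg /= n_batch

    breakdown = {"primary": primary, "aux_skipped": 0}
    tap_grads: dict[str, np.ndarray] = {}
    total = primary

    if sup.enabled and sup.aux_weight > 0:
        labels_ds: dict[int, list[Signal1D]] = {}
        for name in sup.tap_names:
            pooled = taps[name]  # (N, C, T_l)
            t_l = pooled.shape[2]
            if t_l not in labels_ds:
                labels_ds[t_l] = [
                    downsample_label(Signal1D(labels[i], fs), t_l)
                    for i in range(n_batch)
                ]
            tap_sum, grads = 0.0, np.zeros(pooled.shape, dtype=float)
            kept = 0
            for i in range(n_batch):
                term = _aux_term(
                    np.asarray(pooled[i], dtype=float),
                    fs * t_l / t,
                    labels_ds[t_l][i],
                    sup.aux_loss,
                    band,
                    sup.channel_mode,
                )
                if term is None:
                    breakdown["aux_skipped"] += 1
                    logger.warning("skipping degenerate tap trace at %s", name)
                    continue
                value, grad = term
                tap_sum += value
                grads[i] = grad
                kept += 1
            tap_mean = tap_sum / n_batch if kept else 0.0
            breakdown[f"aux/{name}"] = tap_mean
            total += sup.aux_weight * tap_mean
            tap_grads[name] = sup.aux_weight * grads / n_batch

    return total, breakdown, d_rppg, tap_grads


def composite_loss(rppg: Signal1D, taps, label: Signal1D,
                   sup: SupervisionConfig, band: BandpassSpec = HR_BAND):
    """Single-clip composite loss: (total, breakdown). Taps are TapOutputs."""
    tap_arrays = {tap.layer_name: np.asarray(tap.pooled)[None] for tap in taps}
    total, breakdown, _, _ = composite_loss_batch(
        rppg.values[None], tap_arrays, label.values[None], rppg.fs, sup, band
    )
    return total, breakdown
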