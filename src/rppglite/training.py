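"""Training loop: Adam on the composite (primary + deep supervision) loss.

Defaults follow the published recipe: Adam, learning rate 1e-4, weight-decay
coefficient 0.1, batch size 6, 100 epochs. Validation heart-rate RMSE is
computed every epoch with the STFT estimator so convergence can be expressed
as epochs-to-reach a bpm threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import estimate_hr, preprocess_signal
from .network import RppgEncoderDecoder
from .nn import Adam
from .signal import BandpassSpec, HR_BAND, Signal1D
from .supervision import SupervisionConfig, composite_loss_batch

__all__ = ["TrainConfig", "TrainHistory", "train", "validate_hr_rmse"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    weight_decay: float = 0.1
    batch_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "weight_decay": self.weight_decay,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch record of losses and validation heart-rate RMSE."""

    total: list[float] = field(default_factory=list)
    primary: list[float] = field(default_factory=list)
    aux: dict[str, list[float]] = field(default_factory=dict)
    val_rmse: list[float] = field(default_factory=list)

    def epochs_to_threshold(self, th_bpm: float) -> float:
        """First (1-based) epoch whose validation RMSE is below the threshold.

        Returns ``inf`` when the threshold was never reached, so medians
        across runs remain well defined.
        """
        for epoch, rmse in enumerate(self.val_rmse, start=1):
            if rmse is not None and not math.isnan(rmse) and rmse < th_bpm:
                return float(epoch)
        return math.inf

    def to_dataframe(self) -> pd.DataFrame:
        data = {"epoch": np.arange(1, len(self.total) + 1),
                "total": self.total, "primary": self.primary}
        for name, values in self.aux.items():
            data[f"aux_{name}"] = values
        data["val_rmse"] = self.val_rmse
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "epochs": len(self.total),
            "final_total": self.total[-1] if self.total else None,
            "final_primary": self.primary[-1] if self.primary else None,
            "final_val_rmse": self.val_rmse[-1] if self.val_rmse else None,
            "best_val_rmse": (
                float(np.nanmin([v for v in self.val_rmse if v is not None]))
                if any(v is not None for v in self.val_rmse) else None
            ),
        }


def _hr_from_signal(sig: Signal1D, band: BandpassSpec, window_s: float,
                    step_s: float) -> np.ndarray:
    pre = preprocess_signal(sig, band)
    return estimate_hr(pre, window_s=window_s, step_s=step_s, band=band).hr


def validate_hr_rmse(
    network: RppgEncoderDecoder,
    clips: np.ndarray,
    labels: np.ndarray,
    fs: float,
    band: BandpassSpec = HR_BAND,
    window_s: float | None = None,
    step_s: float = 0.1,
    batch_size: int = 6,
) -> float:
    """Heart-rate RMSE of the network's predictions against the labels.

    Both prediction and reference go through the same preprocessing and STFT
    estimator. ``window_s`` defaults to min(5 s, clip duration).
    """
    t = clips.shape[2]
    duration = t / fs
    if window_s is None:
        window_s = min(5.0, duration)
    errs = []
    for start in range(0, len(clips), batch_size):
        batch = clips[start:start + batch_size]
        rppg, _ = network.forward_batch(batch, training=False)
        for i in range(len(batch)):
            pred_hr = _hr_from_signal(Signal1D(rppg[i].astype(float), fs),
                                      band, window_s, step_s)
            ref_hr = _hr_from_signal(
                Signal1D(labels[start + i].astype(float), fs), band, window_s, step_s
            )
            errs.append(pred_hr - ref_hr)
    diff = np.concatenate(errs)
    return float(np.sqrt(np.mean(diff**2)))


def train(
    network: RppgEncoderDecoder,
    train_clips: np.ndarray,
    train_labels: np.ndarray,
    fs: float,
    sup: SupervisionConfig = SupervisionConfig(),
    tc: TrainConfig = TrainConfig(),
    band: BandpassSpec = HR_BAND,
    val_clips: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    val_window_s: float | None = None,
) -> TrainHistory:
    """Run the training loop; deterministic given the seed.

    Parameters
    ----------
    train_clips : ndarray (n, 3, T, H, W); train_labels : ndarray (n, T)
    val_clips, val_labels : optional held-out split for per-epoch HR RMSE.
    """
    n = len(train_clips)
    if n == 0 or len(train_labels) != n:
        raise ValueError("need matching, nonempty clip and label arrays")
    rng = np.random.default_rng(tc.seed)
    optimizer = Adam(
        network.layers,
        lr=tc.learning_rate,
        weight_decay=tc.weight_decay,
    )
    history = TrainHistory()

    for epoch in range(1, tc.epochs + 1):
        order = rng.permutation(n)
        totals, primaries = [], []
        aux_terms: dict[str, list[float]] = {}
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            batch = np.asarray(train_clips[idx], dtype=np.float32)
            rppg, taps = network.forward_batch(batch, training=True)
            total, breakdown, d_rppg, tap_grads = composite_loss_batch(
                rppg.astype(float), taps, train_labels[idx], fs, sup, band
            )
            if not math.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss {total} at epoch {epoch}, batch {start // tc.batch_size}"
                )
            optimizer.zero_grad()
            network.backward_batch(
                d_rppg.astype(np.float32),
                {k: v.astype(np.float32) for k, v in tap_grads.items()},
            )
            optimizer.step()
            totals.append(total)
            primaries.append(breakdown["primary"])
            for key, value in breakdown.items():
                if key.startswith("aux/"):
                    aux_terms.setdefault(key[4:], []).append(value)

        history.total.append(float(np.mean(totals)))
        history.primary.append(float(np.mean(primaries)))
        for name, values in aux_terms.items():
            history.aux.setdefault(name, []).append(float(np.mean(values)))
        if val_clips is not None and len(val_clips):
            rmse = validate_hr_rmse(
                network, val_clips, val_labels, fs, band,
                window_s=val_window_s, batch_size=tc.batch_size,
            )
        else:
            rmse = None
        history.val_rmse.append(rmse)
    return history
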