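"""scikit-learn style estimator wrapping the network and training loop.

``RppgRegressor`` is the package's top-level surface: ``fit`` takes stacked
clips ``X`` of shape (n, 3, T, H, W) and waveform labels ``y`` of shape
(n, T); ``predict`` returns the predicted rPPG waveforms. It composes with
sklearn model selection and pipelines, while the underlying modules
(network, losses, supervision, evaluation) remain importable on their own.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .config import resolve_config
from .network import RppgEncoderDecoder
from .signal import BandpassSpec, HR_BAND
from .supervision import SupervisionConfig
from .training import TrainConfig, train, validate_hr_rmse

__all__ = ["RppgRegressor"]


class RppgRegressor(BaseEstimator, RegressorMixin):
    """Video-to-waveform regressor with optional spectral deep supervision.

    Parameters
    ----------
    config : str or ChannelConfig, default "dse"
        Channel-width preset or explicit configuration.
    supervision : bool, default True
        Attach the auxiliary spectral loss to every intermediate tap.
    primary_loss, aux_loss : str
        Loss kinds; defaults are MSE for the waveform and negated MCC for
        the taps (minimizing it maximizes the band-limited correlation).
    aux_weight : float, default 0.1
        Weight of each auxiliary term relative to the primary loss.
    epochs, learning_rate, weight_decay, batch_size :
        Adam training hyperparameters (published defaults).
    fs : float, default 30.0
        Frame rate the clips and labels are sampled at, in Hz.
    band_bpm : tuple, default (40, 180)
        Heart-rate passband for the spectral losses and HR scoring.
    seed : int, default 0
        Controls weight initialization and batch order.

    Attributes
    ----------
    network_ : RppgEncoderDecoder
        The trained network.
    history_ : TrainHistory
        Per-epoch losses and validation HR RMSE.
    n_parameters_ : int
        Exact trainable-parameter count.
    """

    def __init__(
        self,
        config="dse",
        supervision: bool = True,
        primary_loss: str = "mse",
        aux_loss: str = "negmcc",
        aux_weight: float = 0.1,
        channel_mode: str = "mean",
        epochs: int = 100,
        learning_rate: float = 1e-4,
        weight_decay: float = 0.1,
        batch_size: int = 6,
        fs: float = 30.0,
        band_bpm: tuple[float, float] = (40.0, 180.0),
        seed: int = 0,
    ) -> None:
        self.config = config
        self.supervision = supervision
        self.primary_loss = primary_loss
        self.aux_loss = aux_loss
        self.aux_weight = aux_weight
        self.channel_mode = channel_mode
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.fs = fs
        self.band_bpm = band_bpm
        self.seed = seed

    def _band(self) -> BandpassSpec:
        lo, hi = self.band_bpm
        return BandpassSpec(lo / 60.0, hi / 60.0)

    def fit(self, X, y, val_X=None, val_y=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=float)
        if X.ndim != 5 or X.shape[1] != 3:
            raise ValueError(f"X must be (n, 3, T, H, W), got {X.shape}")
        if y.shape != (X.shape[0], X.shape[2]):
            raise ValueError(f"y must be (n, T) = {(X.shape[0], X.shape[2])}, got {y.shape}")
        self.network_ = RppgEncoderDecoder(resolve_config(self.config), seed=self.seed)
        self.n_parameters_ = self.network_.count_parameters()
        sup = SupervisionConfig(
            primary_loss=self.primary_loss,
            aux_loss=self.aux_loss,
            aux_weight=self.aux_weight,
            enabled=self.supervision,
            channel_mode=self.channel_mode,
        )
        tc = TrainConfig(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            seed=self.seed,
        )
        self.history_ = train(
            self.network_, X, y, self.fs, sup=sup, tc=tc, band=self._band(),
            val_clips=val_X, val_labels=val_y,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float32)
        outputs = []
        for start in range(0, len(X), self.batch_size):
            rppg, _ = self.network_.forward_batch(X[start:start + self.batch_size])
            outputs.append(rppg)
        return np.concatenate(outputs).astype(float)

    def hr_rmse(self, X, y, window_s: float | None = None) -> float:
        """Heart-rate RMSE (bpm) of predictions against reference waveforms."""
        check_is_fitted(self, "network_")
        return validate_hr_rmse(
            self.network_, np.asarray(X, dtype=np.float32), np.asarray(y, dtype=float),
            self.fs, self._band(), window_s=window_s, batch_size=self.batch_size,
        )
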