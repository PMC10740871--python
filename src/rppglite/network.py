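"""The PhysNet-style 3-D spatiotemporal encoder-decoder.

A (3, T, H, W) clip goes through a stem convolution with kernel (1, 5, 5),
three encoder blocks of 3x3x3 convolutions (2, 4 and 2 layers) with pooling,
and two temporally strided transposed-conv decoder layers that restore the
full temporal length; a 1x1x1 head over the spatially pooled features emits
the T-sample rPPG waveform. Twelve convolutional layers in total.

Temporal/spatial schedule (input T, H, W):

    stem      T        H/2   (spatial pool only)
    encoder1  T/2      H/4
    encoder2  T/4      H/8
    encoder3  T/4      H/16
    decoder1  T/2      H/16
    decoder2  T        H/16

The six block outputs are exposed as *taps*: spatially averaged (C, T_l)
matrices carrying each depth's temporal trace at its effective sampling rate
fs_l = fs * T_l / T. Taps are pure reductions — they add no trainable
parameters — and are where the spectral deep-supervision losses attach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ChannelConfig, LAYER_NAMES, N_CONV_LAYERS, TAP_NAMES, resolve_config
from .nn import layers as _nnl
from .nn import (
    BatchNorm3d,
    Conv3d,
    ELU,
    HeadLinear,
    Layer,
    MaxPool3d,
    ReLU,
    SpatialMean,
    TemporalUpConv,
)
from .signal import Signal1D
from .video import VideoClip

__all__ = [
    "TapOutput",
    "NetworkSpec",
    "RppgEncoderDecoder",
    "build_network",
    "count_parameters",
    "forward",
]

#: Temporal length of each tap relative to the input T (denominator).
TAP_TEMPORAL_DIV = {
    "stem": 1,
    "encoder1": 2,
    "encoder2": 4,
    "encoder3": 4,
    "decoder1": 2,
    "decoder2": 1,
}

TEMPORAL_FACTOR = 4   # input T must divide by this
SPATIAL_FACTOR = 16   # input H, W must divide by this


@dataclass
class TapOutput:
    """Spatially pooled activation of one intermediate layer (one clip)."""

    layer_name: str
    pooled: np.ndarray  # (C, T_l)
    fs_l: float


@dataclass(frozen=True)
class NetworkSpec:
    config: ChannelConfig
    input_shape: tuple[int, int, int, int]  # (3, T, H, W)
    layer_names: tuple[str, ...]
    n_layers: int


class RppgEncoderDecoder:
    """Configurable encoder-decoder network with supervision taps.

    Parameters
    ----------
    config : ChannelConfig or preset name
    seed : int
        Seed of the fan-in-scaled random weight initialization.
    """

    def __init__(self, config="dse", seed: int = 0) -> None:
        self.config = resolve_config(config)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        s = self.config.stem_width
        e1, e2, e3 = self.config.encoder_widths
        d1, d2 = self.config.decoder_widths

        def conv_block(c_in, c_out, kernel=(3, 3, 3)):
            return [Conv3d(c_in, c_out, kernel, rng), BatchNorm3d(c_out), ReLU()]

        self._layers: list[Layer] = []
        self._tap_after: dict[int, str] = {}

        def extend(layers, tap=None):
            self._layers.extend(layers)
            if tap is not None:
                self._tap_after[len(self._layers) - 1] = tap

        extend(conv_block(3, s, (1, 5, 5)) + [MaxPool3d((1, 2, 2))], tap="stem")
        extend(conv_block(s, e1) + conv_block(e1, e1) + [MaxPool3d((2, 2, 2))],
               tap="encoder1")
        enc2 = conv_block(e1, e2)
        for _ in range(3):
            enc2 += conv_block(e2, e2)
        extend(enc2 + [MaxPool3d((2, 2, 2))], tap="encoder2")
        extend(conv_block(e2, e3) + conv_block(e3, e3) + [MaxPool3d((1, 2, 2))],
               tap="encoder3")
        extend([TemporalUpConv(e3, d1, rng), BatchNorm3d(d1), ELU()], tap="decoder1")
        extend([TemporalUpConv(d1, d2, rng), BatchNorm3d(d2), ELU()], tap="decoder2")
        extend([SpatialMean(), HeadLinear(d2, rng)])

        self._tap_shapes: dict[str, tuple] = {}

    # ------------------------------------------------------------------ #

    @property
    def layers(self) -> list[Layer]:
        return self._layers

    def count_parameters(self) -> int:
        """Exact number of trainable scalars (conv weights, biases, BN affine)."""
        return sum(layer.n_params() for layer in self._layers)

    def spec(self, input_shape: tuple[int, int, int, int]) -> NetworkSpec:
        validate_input_shape(input_shape)
        return NetworkSpec(
            config=self.config,
            input_shape=tuple(input_shape),
            layer_names=LAYER_NAMES,
            n_layers=N_CONV_LAYERS,
        )

    # ------------------------------------------------------------------ #

    def forward_batch(
        self,
        x: np.ndarray,
        training: bool = False,
        record_full: bool = False,
    ):
        """Run a (N, 3, T, H, W) batch.

        Returns
        -------
        rppg : ndarray (N, T)
        taps : dict name -> ndarray (N, C, T_l), spatially averaged
        full : dict name -> ndarray (N, C, T_l, H_l, W_l), only if requested
        """
        x = np.asarray(x, dtype=_nnl.DTYPE)
        if x.ndim != 5:
            raise ValueError(f"expected a (N, 3, T, H, W) batch, got shape {x.shape}")
        validate_input_shape(x.shape[1:])
        taps: dict[str, np.ndarray] = {}
        full: dict[str, np.ndarray] = {}
        self._tap_shapes = {}
        for i, layer in enumerate(self._layers):
            x = layer.forward(x, training=training)
            name = self._tap_after.get(i)
            if name is not None:
                taps[name] = x.mean(axis=(3, 4))
                self._tap_shapes[name] = x.shape
                if record_full:
                    full[name] = x
        rppg = x  # (N, T)
        if record_full:
            return rppg, taps, full
        return rppg, taps

    def backward_batch(
        self,
        d_rppg: np.ndarray,
        tap_grads: dict[str, np.ndarray] | None = None,
    ) -> None:
        """Backpropagate output and tap gradients; accumulates into ``grads``.

        ``tap_grads`` holds gradients with respect to the spatially pooled
        taps, shape (N, C, T_l) each; they are injected at the corresponding
        depth (spread uniformly over the pooled spatial positions).
        """
        tap_grads = tap_grads or {}
        grad = d_rppg
        for i in range(len(self._layers) - 1, -1, -1):
            name = self._tap_after.get(i)
            if name is not None and name in tap_grads:
                _, _, _, h, w = self._tap_shapes[name]
                inject = tap_grads[name][:, :, :, None, None] / (h * w)
                grad = grad + inject.astype(_nnl.DTYPE)
            grad = self._layers[i].backward(grad)

    def zero_grad(self) -> None:
        for layer in self._layers:
            layer.zero_grad()

    # ------------------------------------------------------------------ #

    def forward_clip(self, clip: VideoClip, training: bool = False):
        """Run a single VideoClip; returns (Signal1D, list[TapOutput])."""
        t = clip.n_frames
        rppg, taps = self.forward_batch(clip.frames[None], training=training)
        tap_list = [
            TapOutput(
                layer_name=name,
                pooled=taps[name][0],
                fs_l=clip.fs * taps[name].shape[2] / t,
            )
            for name in TAP_NAMES
        ]
        return Signal1D(rppg[0].astype(float), clip.fs), tap_list

    def stem_filters(self) -> np.ndarray:
        """The learned stem kernels, shape (C_out, 3, 1, 5, 5)."""
        return self._layers[0].params["w"].copy()

    # ------------------------------------------------------------------ #

    def get_state(self) -> dict:
        state = {}
        for i, layer in enumerate(self._layers):
            for k, p in layer.params.items():
                state[f"{i}.{k}"] = p.copy()
            if isinstance(layer, BatchNorm3d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, layer in enumerate(self._layers):
            for k in layer.params:
                layer.params[k][...] = state[f"{i}.{k}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


def validate_input_shape(shape) -> None:
    c, t, h, w = shape
    if c != 3:
        raise ValueError(f"axis C: expected 3 input channels, got {c}")
    if t % TEMPORAL_FACTOR:
        raise ValueError(f"axis T: {t} not divisible by {TEMPORAL_FACTOR}")
    if h % SPATIAL_FACTOR:
        raise ValueError(f"axis H: {h} not divisible by {SPATIAL_FACTOR}")
    if w % SPATIAL_FACTOR:
        raise ValueError(f"axis W: {w} not divisible by {SPATIAL_FACTOR}")


def build_network(
    config, input_shape: tuple[int, int, int, int] = (3, 128, 16, 16), seed: int = 0
) -> tuple[NetworkSpec, RppgEncoderDecoder]:
    """Build a network for a given width configuration and input shape."""
    net = RppgEncoderDecoder(config, seed=seed)
    return net.spec(input_shape), net


def count_parameters(config) -> int:
    """Exact trainable-parameter count for a width configuration."""
    return RppgEncoderDecoder(config).count_parameters()


def forward(network: RppgEncoderDecoder, clip: VideoClip):
    """Functional wrapper: (rppg Signal1D, taps) for one clip in eval mode."""
    return network.forward_clip(clip, training=False)
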