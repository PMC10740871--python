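"""Channel-width configurations of the spatiotemporal encoder-decoder.

The topology is fixed (12 convolutional layers: one stem, three encoder
blocks of 2/4/2 convs, two temporal-upsampling decoder layers, one output
head); the widths are the architecture hyperparameters swept during model
compression. Two named presets matter:

``baseline``
    The PhysNet-style starting point: stem 32, encoder blocks 64/64/64,
    decoder layers 64/64 — 866,689 trainable parameters.
``dse``
    The compressed final model: stem and encoders 16, decoders 2 —
    57,087 trainable parameters (a 15x reduction).

An intermediate preset ``encoder16`` (encoders reduced to 16, decoders still
64/64; 77,857 parameters) marks the stop of the encoder sweep before the
decoder sweep begins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["ChannelConfig", "PRESETS", "resolve_config", "LAYER_NAMES", "N_CONV_LAYERS"]

#: Ordered names of the 12 convolutional layers.
LAYER_NAMES = (
    "stem-conv1",
    "encoder1-conv1", "encoder1-conv2",
    "encoder2-conv1", "encoder2-conv2", "encoder2-conv3", "encoder2-conv4",
    "encoder3-conv1", "encoder3-conv2",
    "decoder-conv1", "decoder-conv2",
    "head-conv1",
)
N_CONV_LAYERS = len(LAYER_NAMES)

#: Names of the six supervision tap points (block outputs).
TAP_NAMES = ("stem", "encoder1", "encoder2", "encoder3", "decoder1", "decoder2")


@dataclass(frozen=True)
class ChannelConfig:
    """Stem / encoder / decoder channel widths defining one network."""

    stem_width: int = 16
    encoder_widths: tuple[int, int, int] = (16, 16, 16)
    decoder_widths: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        widths = (self.stem_width, *self.encoder_widths, *self.decoder_widths)
        if len(self.encoder_widths) != 3 or len(self.decoder_widths) != 2:
            raise ValueError("need 3 encoder widths and 2 decoder widths")
        if any(int(w) < 1 for w in widths):
            raise ValueError("all channel widths must be >= 1")
        object.__setattr__(self, "encoder_widths", tuple(int(w) for w in self.encoder_widths))
        object.__setattr__(self, "decoder_widths", tuple(int(w) for w in self.decoder_widths))
        object.__setattr__(self, "stem_width", int(self.stem_width))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_widths"] = list(d["encoder_widths"])
        d["decoder_widths"] = list(d["decoder_widths"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelConfig":
        return cls(
            stem_width=d["stem_width"],
            encoder_widths=tuple(d["encoder_widths"]),
            decoder_widths=tuple(d["decoder_widths"]),
        )

    def with_encoder_width(self, alpha: int) -> "ChannelConfig":
        """Encoder-axis sweep point: stem and all encoder blocks set to alpha."""
        return ChannelConfig(alpha, (alpha, alpha, alpha), self.decoder_widths)

    def with_decoder_width(self, alpha: int) -> "ChannelConfig":
        """Decoder-axis sweep point: both decoder layers set to alpha."""
        return ChannelConfig(self.stem_width, self.encoder_widths, (alpha, alpha))


PRESETS: dict[str, ChannelConfig] = {
    "baseline": ChannelConfig(32, (64, 64, 64), (64, 64)),
    "encoder16": ChannelConfig(16, (16, 16, 16), (64, 64)),
    "dse": ChannelConfig(16, (16, 16, 16), (2, 2)),
}


def resolve_config(config) -> ChannelConfig:
    """Accept a ChannelConfig, a preset name, or a mapping."""
    if isinstance(config, ChannelConfig):
        return config
    if isinstance(config, str):
        try:
            return PRESETS[config]
        except KeyError:
            raise ValueError(
                f"unknown preset {config!r}; available: {sorted(PRESETS)}"
            ) from None
    if isinstance(config, dict):
        return ChannelConfig.from_dict(config)
    raise TypeError(f"cannot interpret {type(config).__name__} as a ChannelConfig")
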