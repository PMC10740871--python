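"""Adam optimizer with L2-style weight decay (decay added to the gradient)."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.weight_decay:
                    g = g + self.weight_decay * p
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
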