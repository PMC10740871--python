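"""Minimal numpy layers for 3-D spatiotemporal networks.

Each layer implements ``forward(x, training)`` and ``backward(dout)`` with
explicit derivatives; trainable arrays live in ``layer.params`` and their
gradients, accumulated by ``backward``, in ``layer.grads``. Shapes follow the
video convention (N, C, T, H, W). Convolutions are stride-1 with 'same'
padding, realized as an im2col matrix product; temporal upsampling is a
transposed convolution with kernel (4, 1, 1), stride (2, 1, 1), padding
(1, 0, 0), which exactly doubles T.

Everything runs in float32; correctness of every backward pass is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

DTYPE = np.float32


class Layer:
    """Base class: stateless by default, no parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Conv3d(Layer):
    """3-D convolution, stride 1, 'same' zero padding, with bias.

    Implemented as an accumulation of small channel GEMMs over the kernel
    offsets, on channel-last buffers: for each offset (a, b, c) of the
    kernel, a contiguous slab of the padded input is multiplied by the
    (C_in, C_out) weight slice and accumulated. This keeps every copy
    memcpy-like, which is what makes CPU training feasible.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        kt, kh, kw = kernel
        fan_in = c_in * kt * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kt, kh, kw))
        self.params = {"w": w.astype(DTYPE), "b": np.zeros(c_out, dtype=DTYPE)}
        self.zero_grad()

    def _offsets(self):
        kt, kh, kw = self.kernel
        for a in range(kt):
            for b in range(kh):
                for c in range(kw):
                    yield a, b, c

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, t, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        kt, kh, kw = self.kernel
        pt, ph, pw = kt // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        # channel-last contiguous buffer (N, Tp, Hp, Wp, C)
        xt = np.ascontiguousarray(xp.transpose(0, 2, 3, 4, 1))
        wk = self.params["w"]
        out = np.zeros((n, t, h, w, self.c_out), dtype=DTYPE)
        flat = out.reshape(-1, self.c_out)
        for a, b, cc in self._offsets():
            slab = np.ascontiguousarray(
                xt[:, a:a + t, b:b + h, cc:cc + w, :]
            ).reshape(-1, self.c_in)
            flat += slab @ wk[:, :, a, b, cc].T
        out += self.params["b"]
        if training:
            self._cache = (xt, (n, t, h, w))
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xt, (n, t, h, w) = self._cache
        kt, kh, kw = self.kernel
        pt, ph, pw = kt // 2, kh // 2, kw // 2
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(
            -1, self.c_out
        )
        self.grads["b"] += dmat.sum(axis=0)
        dxt = np.zeros_like(xt)
        wk = self.params["w"]
        dw = self.grads["w"]
        for a, b, cc in self._offsets():
            slab = np.ascontiguousarray(
                xt[:, a:a + t, b:b + h, cc:cc + w, :]
            ).reshape(-1, self.c_in)
            dw[:, :, a, b, cc] += dmat.T @ slab
            dslab = (dmat @ wk[:, :, a, b, cc]).reshape(n, t, h, w, self.c_in)
            dxt[:, a:a + t, b:b + h, cc:cc + w, :] += dslab
        dxp = dxt.transpose(0, 4, 1, 2, 3)
        return np.ascontiguousarray(dxp[:, :, pt:pt + t, ph:ph + h, pw:pw + w])


class TemporalUpConv(Layer):
    """Transposed conv, kernel (4,1,1), stride (2,1,1), pad (1,0,0): T -> 2T."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 4
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 4))
        self.params = {"w": w.astype(DTYPE), "b": np.zeros(c_out, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, t, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        wk = self.params["w"]
        # z_k[n,o,t,h,w] = sum_i x[n,i,t,h,w] * w[i,o,k]
        z = np.einsum("nithw,iok->nokthw", x, wk, optimize=True)
        out = np.zeros((n, self.c_out, 2 * t, h, w), dtype=DTYPE)
        out[:, :, 0::2] += z[:, :, 1]                      # j = 2t,   tap k=1
        out[:, :, 2::2] += z[:, :, 3, :-1]                 # j = 2t+2, tap k=3
        out[:, :, 1::2] += z[:, :, 2]                      # j = 2t+1, tap k=2
        out[:, :, 1:2 * t - 2:2] += z[:, :, 0, 1:]         # j = 2t-1, tap k=0
        out += self.params["b"][None, :, None, None, None]
        if training:
            self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, t, h, w = x.shape
        de = dout[:, :, 0::2]   # gradients at even outputs j = 2t
        do = dout[:, :, 1::2]   # gradients at odd outputs  j = 2t+1
        dz = np.zeros((n, self.c_out, 4, t, h, w), dtype=DTYPE)
        dz[:, :, 1] = de
        dz[:, :, 3, :-1] = de[:, :, 1:]
        dz[:, :, 2] = do
        dz[:, :, 0, 1:] = do[:, :, :-1]
        self.grads["w"] += np.einsum("nithw,nokthw->iok", x, dz, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2, 3, 4))
        return np.einsum("nokthw,iok->nithw", dz, self.params["w"], optimize=True)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, T, H, W) with affine scale."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params = {"gamma": np.ones(c, dtype=DTYPE), "beta": np.zeros(c, dtype=DTYPE)}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None, None]) * inv_std[None, :, None, None, None]
        out = (
            self.params["gamma"][None, :, None, None, None] * xhat
            + self.params["beta"][None, :, None, None, None]
        )
        self._cache = (xhat, inv_std, training)
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, was_training = self._cache
        axes = (0, 2, 3, 4)
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        g = self.params["gamma"][None, :, None, None, None]
        if not was_training:
            return dout * g * inv_std[None, :, None, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dxhat = dout * g
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (inv_std[None, :, None, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._cache = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._cache


class ELU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(x)).astype(DTYPE)
        self._cache = (x > 0, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pos, out = self._cache
        return dout * np.where(pos, 1.0, out + 1.0).astype(DTYPE)


class MaxPool3d(Layer):
    """Non-overlapping max pooling; kernel equals stride."""

    def __init__(self, kernel: tuple[int, int, int]) -> None:
        super().__init__()
        self.kernel = kernel

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, t, h, w = x.shape
        kt, kh, kw = self.kernel
        for axis, k, name in ((t, kt, "T"), (h, kh, "H"), (w, kw, "W")):
            if axis % k:
                raise ValueError(f"axis {name} of size {axis} not divisible by pool {k}")
        to, ho, wo = t // kt, h // kh, w // kw
        r = x.reshape(n, c, to, kt, ho, kh, wo, kw).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        flat = r.reshape(n, c, to, ho, wo, kt * kh * kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        n, c, t, h, w = x_shape
        kt, kh, kw = self.kernel
        to, ho, wo = t // kt, h // kh, w // kw
        dflat = np.zeros((n, c, to, ho, wo, kt * kh * kw), dtype=DTYPE)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dr = dflat.reshape(n, c, to, ho, wo, kt, kh, kw).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(dr.reshape(n, c, t, h, w))


class SpatialMean(Layer):
    """(N, C, T, H, W) -> (N, C, T) by averaging over space."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, t, h, w = self._cache
        return np.broadcast_to(
            dout[:, :, :, None, None] / (h * w), (n, c, t, h, w)
        ).astype(DTYPE)


class HeadLinear(Layer):
    """1x1x1 output convolution over a spatially pooled tensor.

    Maps (N, C, T) -> (N, T) with one weight per channel plus a bias —
    identical in parameter count and effect to a 1-channel 1x1x1 conv applied
    after global spatial pooling.
    """

    def __init__(self, c_in: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in = c_in
        w = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in,))
        self.params = {"w": w.astype(DTYPE), "b": np.zeros(1, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x
        return np.einsum("nct,c->nt", x, self.params["w"]) + self.params["b"][0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["w"] += np.einsum("nct,nt->c", x, dout)
        self.grads["b"] += np.array([dout.sum()], dtype=DTYPE)
        return np.einsum("nt,c->nct", dout, self.params["w"]).astype(DTYPE)
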