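"""Minimal NumPy layers with explicit forward/backward passes.

The network here is small and its topology is fixed, so instead of a general
autodiff graph each layer caches what its backward pass needs and the
composite modules wire gradients by hand.  Convolutions use im2col backed by
``sliding_window_view`` so the inner loop is a single BLAS GEMM; all
parameters and activations are float32.

Conventions: activations are ``(N, C, H, W)`` for images and ``(N, D)`` for
vectors; ``backward`` consumes the loss gradient w.r.t. the layer output and
returns the gradient w.r.t. its input, accumulating parameter gradients on
:class:`Parameter` objects in place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "GroupNorm",
    "FeatureNorm",
    "Dense",
]


class Parameter:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _he_init(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int
) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """Same-padded, stride-1 2-D convolution (square odd kernel)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        *,
        rng: np.random.Generator,
        name: str = "conv",
    ):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _he_init(rng, (out_channels, fan_in), fan_in), f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int, int] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {c}"
            )
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )
        out = cols @ self.weight.value.T + self.bias.value
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        else:
            self._cols = None
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.out_channels
        )
        self.weight.grad += dflat.T @ self._cols
        self.bias.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.weight.value).reshape(n, h, w, c, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,H,W,k,k
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; ties resolve to the first maximum."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size must be even for 2x2 pooling, got {h}x{w}")
        xr = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._shape = arg, (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(d4, self._arg[..., None], dout[..., None], axis=-1)
        return (
            d4.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class GlobalAvgPool(Layer):
    """Mean over the spatial dimensions: (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / np.float32(h * w), (n, c, h, w)
        ).astype(np.float32)


class GlobalMaxPool(Layer):
    """Max over the spatial dimensions: (N, C, H, W) -> (N, C).

    Unlike a spatial average, the maximum preserves the response of a filter
    that fires strongly on a small local structure, however small its area.
    """

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._shape = arg, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        return dflat.reshape(n, c, h, w)


class GroupNorm(Layer):
    """Group normalisation with per-channel affine parameters.

    Channels are split into groups and each (sample, group) slab is
    standardised over its channels and spatial positions, then scaled and
    shifted per channel.  Unlike batch statistics this is independent of
    batch composition, so inference is deterministic and identical to
    training mode.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5,
                 name: str = "gn"):
        if channels % min(groups, channels):
            groups = 1
        self.groups = min(groups, channels)
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), f"{name}.beta")

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(xg.var(axis=2, keepdims=True) + self.eps)
        xhat = ((xg - mu) * inv).reshape(n, c, h, w).astype(np.float32)
        out = self.gamma.value[None, :, None, None] * xhat
        out += self.beta.value[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv.astype(np.float32)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        g = self.groups
        xhat = self._xhat
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = (dout * self.gamma.value[None, :, None, None]).reshape(n, g, -1)
        xh = xhat.reshape(n, g, -1)
        dx = (
            dxhat
            - dxhat.mean(axis=2, keepdims=True)
            - xh * (dxhat * xh).mean(axis=2, keepdims=True)
        ) * self._inv
        return dx.reshape(n, c, h, w).astype(np.float32)


class FeatureNorm(Layer):
    """Per-sample standardisation of a feature vector (layer norm, no affine).

    (N, D) -> (N, D) with zero mean and unit variance along D.  Applied to
    the pooled multi-scale vector it removes global activation shifts and
    scales — e.g. those induced by an intensity-inverted modality — before
    the descriptor head, and keeps the head's inputs well conditioned.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        out = ((x - mu) * inv).astype(np.float32)
        if train:
            self._out, self._inv = out, inv.astype(np.float32)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        y, inv = self._out, self._inv
        return (
            dout - dout.mean(axis=1, keepdims=True)
            - y * (dout * y).mean(axis=1, keepdims=True)
        ) * inv


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        *,
        rng: np.random.Generator,
        name: str = "dense",
    ):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            _he_init(rng, (out_features, in_features), in_features), f"{name}.weight"
        )
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), f"{name}.bias")

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value
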