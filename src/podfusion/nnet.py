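"""A small, self-contained NumPy CNN engine.

Implements exactly the layers the residual classifier needs — 2-D
convolution (im2col), batch normalization, ReLU, global average pooling and a
linear head — each with a hand-written backward pass, plus Adam and the
softmax cross-entropy loss.  Arrays are NCHW internally.  The engine is
deliberately minimal: no autograd graph, just forward caches consumed by the
matching backward call.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Layer:
    """Base layer: forward/backward plus an iterator over (param, grad) pairs."""

    def parameters(self):
        return iter(())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold (N, C, H, W) into (N*Ho*Wo, C*k*k) patch rows."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return cols, ho, wo


def col2im(
    dcols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int, ho: int, wo: int
) -> np.ndarray:
    """Fold patch-row gradients back onto the (padded) input, accumulating overlaps."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dwin[
                :, :, :, :, i, j
            ]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """2-D convolution (cross-correlation), no bias — batch norm follows."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * kernel * kernel
        self.weight = _he_init(rng, (out_channels, fan_in), fan_in)
        self.dweight = np.zeros_like(self.weight)

    def parameters(self):
        yield self.weight, self.dweight

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        cols, ho, wo = im2col(x, self.kernel, self.stride, self.pad)
        self._cache = (cols, x.shape, ho, wo)
        out = cols @ self.weight.T
        return out.reshape(x.shape[0], ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.dweight[...] = dmat.T @ cols
        dcols = dmat @ self.weight
        return col2im(dcols, x_shape, self.kernel, self.stride, self.pad, ho, wo)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        yield self.gamma, self.dgamma
        yield self.beta, self.dbeta

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class GlobalAvgPool(Layer):
    """Average pool over all spatial positions, (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_init(rng, (out_features, in_features), in_features)
        self.bias = np.zeros(out_features)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def parameters(self):
        yield self.weight, self.dweight
        yield self.bias, self.dbias

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dweight[...] = dout.T @ self._x
        self.dbias[...] = dout.sum(axis=0)
        return dout @ self.weight


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam over an ordered parameter list; updates arrays in place."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
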