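"""Minimal NumPy neural-network engine for the 1-D convolutional autoencoder.

Implements exactly the layers the imputation network needs — 1-D
convolution (im2col + BLAS matmul), ReLU, layer/batch normalization,
non-overlapping max-pooling, nearest-repeat upsampling, inverted dropout —
with hand-written backward passes, plus an Adam optimizer with L2 weight
decay. Arrays are channels-first float32: (batch, channels, length).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "LayerNorm",
    "BatchNorm",
    "MaxPool2",
    "Upsample2",
    "Dropout",
    "Adam",
    "softmax_cross_entropy",
]


class Layer:
    """Base class: params/grads are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _windows(xp: np.ndarray, k: int) -> np.ndarray:
    """Sliding length-k windows along the last axis: (N,C,L') -> (N,C,L'-k+1,k)."""
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)


class Conv1D(Layer):
    """Same-padding 1-D convolution, stride 1, odd kernel."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad = kernel // 2
        # He initialization for ReLU stacks
        std = np.sqrt(2.0 / (c_in * kernel))
        w = rng.normal(0.0, std, size=(c_out, c_in, kernel)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        w, b = self.params
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = _windows(xp, self.kernel)  # (N, C_in, L, K)
        if training:
            self._cols = cols
        n, _, length, _ = cols.shape
        flat = cols.transpose(0, 2, 1, 3).reshape(n * length, self.c_in * self.kernel)
        y = flat @ w.reshape(self.c_out, -1).T + b
        return np.ascontiguousarray(
            y.reshape(n, length, self.c_out).transpose(0, 2, 1)
        )

    def backward(self, gy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        cols = self._cols
        assert cols is not None, "backward before forward(training=True)"
        n, _, length, _ = cols.shape
        g = gy.transpose(0, 2, 1).reshape(n * length, self.c_out)
        flat = cols.transpose(0, 2, 1, 3).reshape(n * length, self.c_in * self.kernel)
        self.grads[0][...] = (g.T @ flat).reshape(w.shape)
        self.grads[1][...] = gy.sum(axis=(0, 2))
        # input gradient: full correlation with the flipped kernel; with
        # same padding and odd K the arithmetic is symmetric.
        gp = np.pad(gy, ((0, 0), (0, 0), (self.pad, self.pad)))
        gcols = _windows(gp, self.kernel)  # (N, C_out, L, K)
        gflat = gcols.transpose(0, 2, 1, 3).reshape(n * length, self.c_out * self.kernel)
        w_flip = w[:, :, ::-1].transpose(1, 0, 2).reshape(self.c_in, -1)
        gx = gflat @ w_flip.T
        self._cols = None
        return np.ascontiguousarray(gx.reshape(n, length, self.c_in).transpose(0, 2, 1))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class LayerNorm(Layer):
    """Normalize across channels at each (sample, position); learnable
    per-channel gain and bias."""

    def __init__(self, channels: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        g = np.ones(channels, dtype=np.float32)
        b = np.zeros(channels, dtype=np.float32)
        self.params = [g, b]
        self.grads = [np.zeros_like(g), np.zeros_like(b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._xhat, self._inv = xhat, inv
        g, b = self.params
        return g[None, :, None] * xhat + b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g, _ = self.params
        xhat, inv = self._xhat, self._inv
        self.grads[0][...] = (gy * xhat).sum(axis=(0, 2))
        self.grads[1][...] = gy.sum(axis=(0, 2))
        c = gy.shape[1]
        gxhat = gy * g[None, :, None]
        gx = (
            gxhat
            - gxhat.mean(axis=1, keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=1, keepdims=True)
        ) * inv
        return gx.astype(np.float32, copy=False)


class BatchNorm(Layer):
    """Per-channel normalization over (batch, length); running statistics
    used at evaluation time. Provided for the batch-normalization ablation."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        g = np.ones(channels, dtype=np.float32)
        b = np.zeros(channels, dtype=np.float32)
        self.params = [g, b]
        self.grads = [np.zeros_like(g), np.zeros_like(b)]
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        g, b = self.params
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None]) * inv[None, :, None]
            self._xhat, self._inv, self._count = xhat, inv, x.shape[0] * x.shape[2]
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None]) * inv[None, :, None]
        return g[None, :, None] * xhat + b[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g, _ = self.params
        xhat, inv, cnt = self._xhat, self._inv, self._count
        self.grads[0][...] = (gy * xhat).sum(axis=(0, 2))
        self.grads[1][...] = gy.sum(axis=(0, 2))
        gxhat = gy * g[None, :, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
        ) * inv[None, :, None]
        return gx.astype(np.float32, copy=False)


class MaxPool2(Layer):
    """Non-overlapping max pooling with factor 2; length must be even."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, length = x.shape
        if length % 2:
            raise ValueError("MaxPool2 needs an even length (pad upstream)")
        pairs = x.reshape(n, c, length // 2, 2)
        idx = pairs.argmax(axis=3)
        if training:
            self._idx, self._shape = idx, x.shape
        return pairs.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, half = gy.shape
        gx = np.zeros((n, c, half, 2), dtype=gy.dtype)
        np.put_along_axis(gx, self._idx[..., None], gy[..., None], axis=3)
        return gx.reshape(self._shape)


class Upsample2(Layer):
    """Repeat each position twice along the length axis."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, length = gy.shape
        return gy.reshape(n, c, length // 2, 2).sum(axis=3)


class Dropout(Layer):
    """Inverted dropout: active only in training; identity at evaluation."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return gy
        return gy * self._mask


class Adam:
    """Adam with (classic) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params, self.grads = params, grads
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_cross_entropy(
    logits: np.ndarray, target_codes: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over positions with a known target genotype.

    logits: (N, 3, L) raw class scores for codes {1,2,3}; target_codes:
    (N, L) integers in {0,1,2,3} where 0 marks unknown truth excluded from
    the loss. Returns (loss, dloss/dlogits).
    """
    known = target_codes > 0
    n_known = int(known.sum())
    if n_known == 0:
        raise ValueError("no known genotypes to train on in this window")
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    cls = np.clip(target_codes - 1, 0, 2)
    n, _, length = logits.shape
    idx_n, idx_l = np.nonzero(known)
    picked = p[idx_n, cls[known], idx_l]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    grad = p.copy()
    grad[idx_n, cls[known], idx_l] -= 1.0
    grad *= known[:, None, :]
    grad /= n_known
    return loss, grad.astype(np.float32, copy=False)
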