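"""Minimal NumPy neural-network engine used by the score network.

Implements exactly the pieces the model needs — 2-D convolution with "same"
padding (im2col + GEMM), batch normalization with an optional spatial
validity mask (so padded cells of a variable-length mini-batch never enter
the statistics), LeakyReLU, and the Adam optimizer — with hand-written
backward passes. Layers are functional: ``forward`` returns ``(out, cache)``
and ``backward(grad, cache)`` accumulates parameter gradients and returns the
input gradient, which makes weight-shared (recurrent) blocks trivial: call
the same layer instance once per pass and run the caches backwards.

Array layout is channels-last, (batch, height, width, channels) — it matches
the pairwise relation encoding and keeps im2col and the readout free of
transposes. dtype is float32 by default.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "BatchNorm2d", "LeakyReLU", "Adam"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray) -> None:
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """k x k convolution with same-padding (odd k), He-normal init.

    Weights are stored (out_channels, in_channels, k, k); activations are
    channels-last.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        name: str = "conv",
        dtype=np.float32,
    ) -> None:
        if k < 1 or k % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        fan_in = cin * k * k
        self.k = k
        self.W = Param(
            f"{name}.W",
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)).astype(dtype),
        )
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=dtype))

    def _weight_matrix(self) -> np.ndarray:
        # (O, C, k, k) -> (O, C*k*k) matching the im2col column order (C, k, k)
        return self.W.value.reshape(self.W.value.shape[0], -1)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        k, p = self.k, self.k // 2
        if k == 1:
            return x.reshape(B * H * W, C)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B,H,W,C,k,k)
        return np.ascontiguousarray(cols).reshape(B * H * W, C * k * k)

    def forward(self, x: np.ndarray):
        B, H, W, C = x.shape
        O = self.W.value.shape[0]
        cols = self._im2col(x)
        out = (cols @ self._weight_matrix().T + self.b.value).reshape(B, H, W, O)
        return out, (cols, x.shape)

    def backward(self, g: np.ndarray, cache) -> np.ndarray:
        cols, xshape = cache
        B, H, W, C = xshape
        O = self.W.value.shape[0]
        k, p = self.k, self.k // 2
        gm = g.reshape(-1, O)
        self.W.grad += (gm.T @ cols).reshape(self.W.value.shape)
        self.b.grad += gm.sum(axis=0)
        dcols = gm @ self._weight_matrix()
        if k == 1:
            return dcols.reshape(B, H, W, C)
        dcols = dcols.reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=g.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, u : u + H, v : v + W, :] += dcols[:, :, :, :, u, v]
        return dxp[:, p : p + H, p : p + W, :]

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm2d:
    """Per-channel batch normalization over (B, H, W).

    With a spatial ``mask`` (B, H, W, 1) of {0, 1}, statistics are taken over
    masked-in cells only and the output is zeroed at masked-out cells; a
    padded mini-batch therefore behaves exactly like the unpadded samples.
    """

    def __init__(
        self, c: int, name: str = "bn", momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32
    ) -> None:
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, mask: np.ndarray | None, training: bool):
        g, b = self.gamma.value, self.beta.value
        if not training:
            std = np.sqrt(self.running_var + self.eps)
            out = g * ((x - self.running_mean) / std) + b
            if mask is not None:
                out = out * mask
            return out, None
        if mask is None:
            m = float(x.shape[0] * x.shape[1] * x.shape[2])
            mean = x.mean(axis=(0, 1, 2))
            xc = x - mean
            var = (xc * xc).mean(axis=(0, 1, 2))
        else:
            m = float(mask.sum())
            if m <= 1:
                raise ValueError("batch-norm mask selects <= 1 cell")
            mean = (x * mask).sum(axis=(0, 1, 2)) / m
            xc = (x - mean) * mask
            var = (xc * xc).sum(axis=(0, 1, 2)) / m
        self.running_mean += self.momentum * (mean - self.running_mean)
        self.running_var += self.momentum * (var - self.running_var)
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = xc / std
        out = g * xhat + b
        if mask is not None:
            out = out * mask
        return out, (xhat, std, mask, m)

    def backward(self, gout: np.ndarray, cache) -> np.ndarray:
        xhat, std, mask, m = cache
        if mask is not None:
            gout = gout * mask
        self.beta.grad += gout.sum(axis=(0, 1, 2))
        self.gamma.grad += (gout * xhat).sum(axis=(0, 1, 2))
        dxhat = gout * self.gamma.value
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (dxhat - s1 / m - xhat * (s2 / m)) / std
        if mask is not None:
            dx = dx * mask
        return dx

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class LeakyReLU:
    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope

    def forward(self, x: np.ndarray):
        pos = x >= 0
        return np.where(pos, x, self.slope * x), pos

    def backward(self, g: np.ndarray, cache) -> np.ndarray:
        pos = cache
        return np.where(pos, g, self.slope * g)


class Adam:
    """Adam with the standard bias correction (betas 0.9/0.999, eps 1e-8)."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self._v = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            grad = p.grad.astype(np.float64)
            m += (1.0 - self.b1) * (grad - m)
            v += (1.0 - self.b2) * (grad * grad - v)
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value -= update.astype(p.value.dtype)
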