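"""Minimal NumPy building blocks for 1-D convolutional sequence models.

Implements exactly what the ground-contact classifier needs: length-
preserving ("same"-padded) 1-D convolution, batch normalization over the
(batch, time) axes, ReLU, a numerically stable sigmoid / binary
cross-entropy pair, and Adam. Every layer carries an explicit backward
pass; the convolution is evaluated as one BLAS contraction per kernel tap,
which is fast for the small kernels (k <= 7) used here.

All computation is float32. Layers cache what their backward pass needs on
``self``; the model is single-threaded by design.
"""

from __future__ import annotations

import numpy as np

from sprintgc.errors import ValidationError


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


def kaiming_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    """Kaiming-uniform (fan-in, ReLU gain) initialization."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv1dSame:
    """1-D convolution with symmetric zero padding preserving length.

    Odd kernels only: padding (k-1)/2 on both sides. Bias is omitted by
    default because every convolution here is followed by batch
    normalization, which absorbs it; the classifier head enables it.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if kernel_size % 2 != 1:
            raise ValidationError("kernel_size must be odd for symmetric same-padding")
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2
        self.weight = Parameter(
            kaiming_uniform((out_channels, in_channels, kernel_size), fan_in, rng),
            name=f"{name}.weight",
        )
        self.bias = (
            Parameter(np.zeros(out_channels, dtype=np.float32), name=f"{name}.bias")
            if bias
            else None
        )
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValidationError(
                f"expected (N, {self.in_channels}, L) input, got {x.shape}"
            )
        N, _, L = x.shape
        k, p = self.kernel_size, self.pad
        if p:
            xp = np.zeros((N, self.in_channels, L + 2 * p), dtype=np.float32)
            xp[:, :, p : p + L] = x
        else:
            xp = np.asarray(x, dtype=np.float32)
        y = np.zeros((N, self.out_channels, L), dtype=np.float32)
        W = self.weight.data
        for j in range(k):
            y += np.einsum("oi,nil->nol", W[:, :, j], xp[:, :, j : j + L], optimize=True)
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        self._xp = xp if cache else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called without cached forward")
        N, _, Lp = xp.shape
        L = dy.shape[2]
        k, p = self.kernel_size, self.pad
        W = self.weight.data
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        dxp = np.zeros_like(xp)
        for j in range(k):
            self.weight.grad[:, :, j] += np.einsum(
                "nol,nil->oi", dy, xp[:, :, j : j + L], optimize=True
            )
            dxp[:, :, j : j + L] += np.einsum(
                "oi,nol->nil", W[:, :, j], dy, optimize=True
            )
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        self._xp = None
        return dxp[:, :, p : p + L] if p else dxp

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm1d:
    """Batch normalization over the (batch, time) axes of (N, C, L) input.

    Training mode normalizes with batch statistics and updates running
    statistics (momentum 0.1); eval mode uses the running statistics, so a
    fixed trained model is deterministic at inference. A layer whose
    running statistics were never updated (a freshly initialized model)
    falls back to batch statistics even in eval mode -- the (0, 1)
    placeholders would otherwise leave deep activation stacks
    unnormalized and saturate the classifier head.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.n_updates = 0
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.channels:
            raise ValidationError(f"expected (N, {self.channels}, L), got {x.shape}")
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            self.n_updates += 1
        elif self.n_updates == 0:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        y = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        self._cache = (xhat.astype(np.float32), inv_std.astype(np.float32)) if training else None
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward requires a training-mode forward")
        xhat, inv_std = self._cache
        M = dy.shape[0] * dy.shape[2]
        dgamma = np.einsum("ncl,ncl->c", dy, xhat, optimize=True)
        dbeta = dy.sum(axis=(0, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.data * inv_std
        dx = (
            dy
            - (dbeta / M)[None, :, None]
            - xhat * (dgamma / M)[None, :, None]
        ) * g[None, :, None]
        self._cache = None
        return dx.astype(np.float32)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ReLU forward; returns (output, mask) with mask for backward."""
    mask = x > 0
    return np.where(mask, x, 0.0).astype(np.float32), mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-timestep binary cross-entropy on logits and its gradient."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return float(loss), dz


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            np.multiply(m, b1, out=m)
            m += (1 - b1) * p.grad
            np.multiply(v, b2, out=v)
            v += (1 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
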