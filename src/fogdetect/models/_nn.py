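"""Minimal numpy neural-network layers with explicit backpropagation.

Just enough machinery for small 1-D convolutional classifiers trained on a
CPU: im2col convolutions, max pooling, batch normalization, dropout, dense
layers, an AdamW optimizer, and a class-weighted binary cross-entropy on
logits. All state is float32; every source of randomness (initialization,
shuffling, dropout) flows from a single numpy Generator, so training is a
deterministic function of (data, config, seed).

Layout convention: activations are ``(N, C, L)`` — batch, channels, time.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv1d(Layer):
    """Same-padded 1-D convolution via im2col.

    Padding splits k-1 zeros as (k-1)//2 left, k//2 right, so even kernel
    sizes also preserve length.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.W = Param(_he_init(rng, in_ch * k, (in_ch * k, out_ch)))
        self.b = Param(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.pl = (k - 1) // 2
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        N, C, L = x.shape
        k = self.k
        xp = np.zeros((N, C, L + k - 1), dtype=np.float32)
        xp[:, :, self.pl : self.pl + L] = x
        # (N, L, C, k) -> (N*L, C*k)
        cols = np.empty((N, L, C, k), dtype=np.float32)
        for j in range(k):
            cols[:, :, :, j] = xp[:, :, j : j + L].transpose(0, 2, 1)
        return cols.reshape(N * L, C * k)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, L = x.shape
        cols = self._im2col(x)
        y = cols @ self.W.value
        if self.b is not None:
            y += self.b.value
        if train:
            self._cols, self._shape = cols, (N, C, L)
        return y.reshape(N, L, self.out_ch).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, L = self._shape
        k = self.k
        gy = grad.transpose(0, 2, 1).reshape(N * L, self.out_ch)
        self.W.grad += self._cols.T @ gy
        if self.b is not None:
            self.b.grad += gy.sum(axis=0)
        dcols = (gy @ self.W.value.T).reshape(N, L, C, k)
        dxp = np.zeros((N, C, L + k - 1), dtype=np.float32)
        for j in range(k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        self._cols = None
        return dxp[:, :, self.pl : self.pl + L]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Non-overlapping pooling with stride = size; trailing remainder dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, L = x.shape
        s = self.size
        L2 = L // s
        xr = x[:, :, : L2 * s].reshape(N, C, L2, s)
        arg = xr.argmax(axis=3)
        if train:
            self._arg, self._in_L = arg, L
        return np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, L2 = grad.shape
        s = self.size
        dxr = np.zeros((N, C, L2, s), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((N, C, self._in_L), dtype=np.float32)
        dx[:, :, : L2 * s] = dxr.reshape(N, C, L2 * s)
        return dx


class MaxPoolSame(Layer):
    """Stride-1, length-preserving max pool (used in inception modules)."""

    def __init__(self, size: int = 3):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, L = x.shape
        k = self.size
        pl = (k - 1) // 2
        xp = np.full((N, C, L + k - 1), -np.inf, dtype=np.float32)
        xp[:, :, pl : pl + L] = x
        stack = np.stack([xp[:, :, j : j + L] for j in range(k)], axis=3)
        arg = stack.argmax(axis=3)
        if train:
            self._arg, self._L, self._pl = arg, L, pl
        return np.take_along_axis(stack, arg[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, L = grad.shape
        k = self.size
        dxp = np.zeros((N, C, L + k - 1), dtype=np.float32)
        # scatter grad to the winning offset per position
        for j in range(k):
            sel = self._arg == j
            dxp[:, :, j : j + L] += np.where(sel, grad, 0.0)
        return dxp[:, :, self._pl : self._pl + L]


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time); running stats at eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv[None, :, None]
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[2]
        else:
            inv = 1.0 / np.sqrt(self.run_var + self.eps)
            xhat = (x - self.run_mean[None, :, None]) * inv[None, :, None]
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        gsum = g.sum(axis=(0, 2), keepdims=True)
        gx = (g * xhat).sum(axis=(0, 2), keepdims=True)
        return inv[None, :, None] / m * (m * g - gsum - xhat * gx)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.p <= 0.0:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_he_init(rng, n_in, (n_in, n_out)))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class AdamW:
    """Adam with decoupled weight decay; weight_decay=0 reduces to Adam."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self._params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self._params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self._params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd:
                update = update + self.wd * p.value
            p.value -= self.lr * update


def weighted_bce_with_logits(
    z: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(w * per))
    sig = 1.0 / (1.0 + np.exp(-z))
    dz = (w * (sig - y) / z.shape[0]).astype(np.float32)
    return loss, dz


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def minibatches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]
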