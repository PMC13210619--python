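"""Minimal numpy layer engine for the compact raw-signal EEG baselines.

Implements exactly the pieces the three conv-net baselines need: grouped 1-D
convolution, batch normalisation, ReLU/ELU/square/log activations, max /
average / adaptive-average pooling, dropout, linear layers, Adam, and
binary cross-entropy with logits. Forward/backward passes are explicit;
training runs comfortably on one CPU at the cohort sizes this package
targets.
"""

from __future__ import annotations

import copy

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, L) -> strided view (B, C, L_out, k)."""
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)
    return v[:, :, ::stride, :]


class Conv1d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True):
        if in_ch % groups or out_ch % groups:
            raise ValueError("in_ch and out_ch must be divisible by groups")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_ch // groups) * kernel
        w = rng.standard_normal((out_ch, in_ch // groups, kernel))
        self.w = Param(w * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(out_ch)) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        self._x = x
        win = _windows(x, self.k, self.stride)     # (B, C, Lout, k)
        B, _, Lout, _ = win.shape
        cg = self.in_ch // self.groups
        og = self.out_ch // self.groups
        out = np.empty((B, self.out_ch, Lout))
        for g in range(self.groups):
            wg = self.w.value[g * og:(g + 1) * og]          # (og, cg, k)
            xg = win[:, g * cg:(g + 1) * cg]                 # (B, cg, Lout, k)
            out[:, g * og:(g + 1) * og] = np.einsum(
                "bclk,ock->bol", xg, wg, optimize=True
            )
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out

    def backward(self, gout):
        x = self._x
        win = _windows(x, self.k, self.stride)
        B = x.shape[0]
        cg = self.in_ch // self.groups
        og = self.out_ch // self.groups
        gx = np.zeros_like(x)
        Lout = gout.shape[2]
        for g in range(self.groups):
            wg = self.w.value[g * og:(g + 1) * og]
            xg = win[:, g * cg:(g + 1) * cg]
            go = gout[:, g * og:(g + 1) * og]                # (B, og, Lout)
            self.w.grad[g * og:(g + 1) * og] += np.einsum(
                "bclk,bol->ock", xg, go, optimize=True
            )
            tmp = np.einsum("ock,bol->bclk", wg, go, optimize=True)
            for k in range(self.k):
                gx[:, g * cg:(g + 1) * cg,
                   k:k + self.stride * Lout:self.stride] += tmp[:, :, :, k]
        if self.b is not None:
            self.b.grad += gout.sum(axis=(0, 2))
        if self.padding:
            gx = gx[:, :, self.padding:-self.padding]
        return gx


class BatchNorm1d(Layer):
    # momentum 0.3: with the small per-epoch batch counts this package
    # trains at, slower running averages lag the weights and distort the
    # early-stopping validation loss
    def __init__(self, n_ch: int, momentum: float = 0.3, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps
        self._seen_batch = False

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            # seed running stats from the first batch; a cold start from
            # (0, 1) makes early validation losses meaningless and can trip
            # early stopping before the averages warm up
            m = 1.0 if not self._seen_batch else self.momentum
            self._seen_batch = True
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        self._training = training
        return self.gamma.value[None, :, None] * self._xhat \
            + self.beta.value[None, :, None]

    def backward(self, gout):
        xhat, std = self._xhat, self._std
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2))
        self.beta.grad += gout.sum(axis=(0, 2))
        gxhat = gout * self.gamma.value[None, :, None]
        if not self._training:
            return gxhat / std
        n = xhat.shape[0] * xhat.shape[2]
        return (gxhat - gxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True) / n) / std


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training):
        self._neg = x <= 0
        self._expm = self.alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        return np.where(self._neg, self._expm, x)

    def backward(self, gout):
        return gout * np.where(self._neg, self._expm + self.alpha, 1.0)


class Square(Layer):
    def forward(self, x, training):
        self._x = x
        return x * x

    def backward(self, gout):
        return 2.0 * self._x * gout


class LogCompress(Layer):
    """ln(x + eps); expects nonnegative input (squared, pooled power)."""

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, training):
        self._denom = x + self.eps
        return np.log(self._denom)

    def backward(self, gout):
        return gout / self._denom


class MaxPool1d(Layer):
    def __init__(self, k: int):
        self.k = k

    def forward(self, x, training):
        B, C, L = x.shape
        Lq = L // self.k
        x = x[:, :, :Lq * self.k]
        blocks = x.reshape(B, C, Lq, self.k)
        self._arg = blocks.argmax(axis=-1)
        self._shape = (B, C, L)
        return blocks.max(axis=-1)

    def backward(self, gout):
        B, C, L = self._shape
        Lq = gout.shape[2]
        gx = np.zeros((B, C, Lq, self.k))
        idx = np.indices((B, C, Lq))
        gx[idx[0], idx[1], idx[2], self._arg] = gout
        out = np.zeros((B, C, L))
        out[:, :, :Lq * self.k] = gx.reshape(B, C, Lq * self.k)
        return out


class AvgPool1d(Layer):
    def __init__(self, k: int, stride: int | None = None):
        self.k = k
        self.stride = stride or k

    def forward(self, x, training):
        self._shape = x.shape
        win = _windows(x, self.k, self.stride)
        return win.mean(axis=-1)

    def backward(self, gout):
        gx = np.zeros(self._shape)
        for j in range(gout.shape[2]):
            s = j * self.stride
            gx[:, :, s:s + self.k] += gout[:, :, j:j + 1] / self.k
        return gx


class AdaptiveAvgPool1d(Layer):
    """Global average over time, output length 1."""

    def forward(self, x, training):
        self._L = x.shape[2]
        return x.mean(axis=2, keepdims=True)

    def backward(self, gout):
        return np.repeat(gout / self._L, self._L, axis=2)


class Dropout(Layer):
    def __init__(self, p: float, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Permute(Layer):
    """Fixed channel reordering (used to regroup grouped-conv outputs)."""

    def __init__(self, order: np.ndarray):
        self.order = np.asarray(order)
        self.inverse = np.argsort(self.order)

    def forward(self, x, training):
        return x[:, self.order]

    def backward(self, gout):
        return gout[:, self.inverse]


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        self.w = Param(rng.standard_normal((n_in, n_out))
                       * np.sqrt(2.0 / n_in))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gout):
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p.value[...] = s

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits and its gradient w.r.t. logits."""
    z = logits.ravel()
    y = targets.ravel().astype(float)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = ((1.0 / (1.0 + np.exp(-z))) - y) / z.size
    return float(loss), grad.reshape(logits.shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def clone_state(state: list[np.ndarray]) -> list[np.ndarray]:
    return copy.deepcopy(state)
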