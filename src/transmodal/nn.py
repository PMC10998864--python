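"""Minimal dense neural-network kernel with explicit reverse-mode gradients.

The translator networks used in this package are small multilayer perceptrons
(a few hundred to a few thousand input features, hidden widths of 32-256), so
the forward and backward passes are written directly in numpy.  Layers are
stateless with respect to activations: ``forward`` returns ``(output, cache)``
and ``backward(cache, grad_out)`` accumulates parameter gradients and returns
the gradient with respect to the input.  This lets a single layer object be
applied several times per step (weight sharing) with gradients summed across
uses, which the translator relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "BlockDense",
    "BlockScatterDense",
    "LeakyReLU",
    "Sigmoid",
    "Dropout",
    "InputMask",
    "Sequential",
    "Adam",
    "SGD",
]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _init_dense(n_in: int, n_out: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # uniform(-k, k) with k = 1/sqrt(fan_in), the usual default for dense layers
    k = 1.0 / np.sqrt(n_in)
    w = rng.uniform(-k, k, size=(n_in, n_out))
    b = rng.uniform(-k, k, size=n_out)
    return w, b


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        w, b = _init_dense(n_in, n_out, rng)
        self.W = Param(w)
        self.b = Param(b)
        self.n_in = n_in
        self.n_out = n_out

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ValueError(
                f"input width {x.shape[1]} does not match layer width {self.n_in}"
            )
        return x @ self.W.value + self.b.value, x

    def backward(self, cache, grad_out):
        x = cache
        self.W.grad += x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.W.value.T

    def parameters(self):
        return [self.W, self.b]


class BlockDense:
    """Group-wise dense layer: each feature group maps to its own output block.

    Used for the chromatin encoder, where every chromosome owns an independent
    ``|group| -> out_per_block`` map and the outputs are concatenated.  No
    parameters connect features of different groups.
    """

    def __init__(self, groups, out_per_block: int, rng: np.random.Generator):
        self.groups = [np.asarray(g, dtype=np.intp) for g in groups]
        self.out_per_block = out_per_block
        self.Ws = []
        self.bs = []
        for g in self.groups:
            w, b = _init_dense(len(g), out_per_block, rng)
            self.Ws.append(Param(w))
            self.bs.append(Param(b))
        self.n_in = sum(len(g) for g in self.groups)
        self.n_out = out_per_block * len(self.groups)

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ValueError(
                f"input width {x.shape[1]} does not match grouped width {self.n_in}"
            )
        outs = [
            x[:, g] @ w.value + b.value
            for g, w, b in zip(self.groups, self.Ws, self.bs)
        ]
        return np.concatenate(outs, axis=1), x

    def backward(self, cache, grad_out):
        x = cache
        gx = np.zeros_like(x)
        d = self.out_per_block
        for i, (g, w, b) in enumerate(zip(self.groups, self.Ws, self.bs)):
            go = grad_out[:, i * d : (i + 1) * d]
            w.grad += x[:, g].T @ go
            b.grad += go.sum(axis=0)
            gx[:, g] += go @ w.value.T
        return gx

    def parameters(self):
        return [p for pair in zip(self.Ws, self.bs) for p in pair]


class BlockScatterDense:
    """Mirror of :class:`BlockDense`: per-group input blocks map back to the
    group's own feature columns (chromatin decoder output layer)."""

    def __init__(self, groups, in_per_block: int, n_features: int, rng: np.random.Generator):
        self.groups = [np.asarray(g, dtype=np.intp) for g in groups]
        self.in_per_block = in_per_block
        self.n_features = n_features
        self.Ws = []
        self.bs = []
        for g in self.groups:
            w, b = _init_dense(in_per_block, len(g), rng)
            self.Ws.append(Param(w))
            self.bs.append(Param(b))
        self.n_in = in_per_block * len(self.groups)
        self.n_out = n_features

    def forward(self, x, *, training=False, rng=None):
        if x.shape[1] != self.n_in:
            raise ValueError(
                f"input width {x.shape[1]} does not match grouped width {self.n_in}"
            )
        out = np.zeros((x.shape[0], self.n_features))
        d = self.in_per_block
        for i, (g, w, b) in enumerate(zip(self.groups, self.Ws, self.bs)):
            out[:, g] = x[:, i * d : (i + 1) * d] @ w.value + b.value
        return out, x

    def backward(self, cache, grad_out):
        x = cache
        gx = np.zeros_like(x)
        d = self.in_per_block
        for i, (g, w, b) in enumerate(zip(self.groups, self.Ws, self.bs)):
            go = grad_out[:, g]
            w.grad += x[:, i * d : (i + 1) * d].T @ go
            b.grad += go.sum(axis=0)
            gx[:, i * d : (i + 1) * d] = go @ w.value.T
        return gx

    def parameters(self):
        return [p for pair in zip(self.Ws, self.bs) for p in pair]


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, *, training=False, rng=None):
        neg = x < 0
        y = np.where(neg, self.slope * x, x)
        return y, neg

    def backward(self, cache, grad_out):
        neg = cache
        return np.where(neg, self.slope * grad_out, grad_out)

    def parameters(self):
        return []


class Sigmoid:
    def forward(self, x, *, training=False, rng=None):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, cache, grad_out):
        y = cache
        return grad_out * y * (1.0 - y)

    def parameters(self):
        return []


class Dropout:
    """Inverted dropout: active only when ``training`` is true."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            return x, None
        keep = rng.random(x.shape) >= self.rate
        scale = 1.0 / (1.0 - self.rate)
        return x * keep * scale, (keep, scale)

    def backward(self, cache, grad_out):
        if cache is None:
            return grad_out
        keep, scale = cache
        return grad_out * keep * scale

    def parameters(self):
        return []


class InputMask:
    """Random zeroing of a fraction of the input entries during training.

    Unlike dropout the surviving entries are *not* rescaled: the corruption
    emulates extra dropout events in the counts, and the encoder is asked to be
    robust to them.  A fresh Bernoulli mask is drawn on every forward call; at
    inference the input passes through untouched.
    """

    def __init__(self, rate: float):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("mask rate must lie in [0, 1]")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            return x, None
        keep = rng.random(x.shape) >= self.rate
        return x * keep, keep

    def backward(self, cache, grad_out):
        if cache is None:
            return grad_out
        return grad_out * cache

    def parameters(self):
        return []


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, *, training=False, rng=None):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, training=training, rng=rng)
            caches.append(c)
        return x, caches

    def backward(self, caches, grad_out):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            grad_out = layer.backward(c, grad_out)
        return grad_out

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        if not hasattr(self, "_buf"):
            self._buf = [(np.empty_like(p.value), np.empty_like(p.value))
                         for p in self.params]
        for p, m, v, (t1, t2) in zip(self.params, self.m, self.v, self._buf):
            m *= b1
            np.multiply(p.grad, 1.0 - b1, out=t1)
            m += t1
            v *= b2
            np.multiply(p.grad, p.grad, out=t1)
            t1 *= 1.0 - b2
            v += t1
            # p -= lr * (m/bias1) / (sqrt(v/bias2) + eps), identical order
            np.divide(v, bias2, out=t1)
            np.sqrt(t1, out=t1)
            t1 += self.eps
            np.divide(m, bias1, out=t2)
            t2 *= self.lr
            t2 /= t1
            p.value -= t2


class SGD:
    """Plain gradient descent (no momentum), used for the discriminators."""

    def __init__(self, params, lr=5e-3):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.value -= self.lr * p.grad


def snapshot(params) -> list[np.ndarray]:
    """Deep-copy parameter values (used for best-epoch restoration)."""
    return [p.value.copy() for p in params]


def restore(params, values) -> None:
    for p, v in zip(params, values):
        p.value[...] = v
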