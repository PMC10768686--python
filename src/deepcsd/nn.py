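"""Minimal neural-network primitives (numpy, explicit backprop).

Dense, batch-norm and ReLU building blocks with hand-written gradients,
plus Adam.  The networks in :mod:`deepcsd.model` are small (3x3x3x45
patches in, 45 coefficients out), so explicit numpy backprop is fast
enough for desk-scale training and keeps runs bit-reproducible on one
worker.  Gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Dense:
    """Affine layer y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He init, ReLU networks
        self.W = Param(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm:
    """Per-feature batch normalization with learned scale and shift.

    Training mode normalizes by batch statistics and updates running
    estimates; eval mode uses the running estimates (so inference is
    deterministic and batch-size independent).
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, n = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if not train:
            return dxhat * inv
        return inv / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class PatchConv3:
    """3x3x3 convolution over a 3x3x3 patch with zero padding 1.

    Weight layout is the standard im2col form W (27 * c_in, c_out) ordered
    by kernel offset then input channel.  Internally the patch-sized
    problem is executed as one dense matmul with a structured
    (27 c_in, 27 c_out) matrix assembled from W, which is much faster than
    gather/scatter at these sizes; gradients are folded back per kernel
    offset.  The structured path matches im2col exactly (tested).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (27 * c_in))
        self.W = Param(rng.normal(0.0, scale, (27 * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        # valid (output position p, kernel offset q, input position i) triples
        gather = conv_gather_indices()
        self._links = [(p, q, int(gather[p, q]))
                       for p in range(27) for q in range(27) if gather[p, q] < 27]
        self._x: np.ndarray | None = None

    def _structured(self, W: np.ndarray) -> np.ndarray:
        T = np.zeros((27 * self.c_in, 27 * self.c_out))
        for p, q, i in self._links:
            T[i * self.c_in:(i + 1) * self.c_in, p * self.c_out:(p + 1) * self.c_out] += \
                W[q * self.c_in:(q + 1) * self.c_in]
        return T

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 27 * c_in) flattened patch -> (N, 27 * c_out)."""
        self._x = x
        self._T = self._structured(self.W.value)
        return x @ self._T + np.tile(self.b.value, 27)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dT = self._x.T @ dy
        dW = np.zeros_like(self.W.value)
        for p, q, i in self._links:
            dW[q * self.c_in:(q + 1) * self.c_in] += \
                dT[i * self.c_in:(i + 1) * self.c_in, p * self.c_out:(p + 1) * self.c_out]
        self.W.grad += dW
        self.b.grad += dy.reshape(-1, 27, self.c_out).sum(axis=(0, 1))
        return dy @ self._T.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


def conv_gather_indices() -> np.ndarray:
    """Index table for the padded 3x3x3 convolution on a 3x3x3 patch.

    Entry (p, q) maps output position p (0..26, C-order) and kernel offset
    q (0..26) to the flat input position, or to 27 (a zero slot) where the
    offset falls outside the patch.
    """
    idx = np.full((27, 27), 27, dtype=np.intp)
    for p, (i, j, k) in enumerate(np.ndindex(3, 3, 3)):
        for q, (di, dj, dk) in enumerate(np.ndindex(3, 3, 3)):
            a, b, c = i + di - 1, j + dj - 1, k + dk - 1
            if 0 <= a < 3 and 0 <= b < 3 and 0 <= c < 3:
                idx[p, q] = (a * 3 + b) * 3 + c
    return idx
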