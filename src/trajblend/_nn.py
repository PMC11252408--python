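"""Minimal NumPy neural-network core.

The three learned stages of the pipeline (fraction autoencoder,
fraction-constrained beta-VAE, Bernoulli-Poisson GCN) are small dense
models; they are implemented here as explicit forward/backward layers
with an Adam optimizer.  Everything is seeded through a caller-supplied
``numpy.random.Generator`` so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Linear", "BatchNorm", "Adam", "relu", "relu_grad",
           "softmax", "softmax_jvp_rows", "softplus", "simplex_softplus",
           "simplex_softplus_backward"]


class Param:
    """A weight array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Linear:
    """Dense layer y = x W + b with He-scaled initialisation."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    @property
    def params(self):
        return [self.W, self.b]


class BatchNorm:
    """Per-feature batch normalisation with learnable scale and shift.

    Used full-batch in the GCN, so batch statistics are also the
    inference statistics.
    """

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.eps = eps
        self._cache = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        n = g.shape[0]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gx = g * self.gamma.value
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / std

    @property
    def params(self):
        return [self.gamma, self.beta]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(g: np.ndarray, pre: np.ndarray) -> np.ndarray:
    return g * (pre > 0.0)


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_jvp_rows(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Backpropagate ``g`` through a row-wise softmax whose output was ``p``."""
    return p * (g - (g * p).sum(axis=-1, keepdims=True))


def softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def simplex_softplus(x: np.ndarray) -> np.ndarray:
    """Row-wise simplex map p = softplus(x) / sum softplus(x).

    Unlike softmax, the gradient toward a coordinate does not vanish when
    its probability reaches zero, so simplex heads trained with
    non-vanishing losses (such as mean absolute error) cannot permanently
    kill a class.
    """
    s = softplus(x)
    return s / s.sum(axis=-1, keepdims=True)


def simplex_softplus_backward(x: np.ndarray, p: np.ndarray,
                              g: np.ndarray) -> np.ndarray:
    """Backpropagate ``g`` through ``simplex_softplus`` given input ``x``
    and output ``p``."""
    s_total = softplus(x).sum(axis=-1, keepdims=True)
    sig = 1.0 / (1.0 + np.exp(-x))
    return sig / s_total * (g - (g * p).sum(axis=-1, keepdims=True))


class Adam:
    """Adam with optional decoupled L2 (added to the gradient, matching the
    classic L2-regularisation formulation used by the GCN stage)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_params=()):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decay_set = {id(p) for p in decay_params}
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and id(p) in self.decay_set:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
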