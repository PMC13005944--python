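"""Minimal dense-network machinery: Adam, initializers, activations.

All models in this package are small (a linear softmax classifier, a
three-layer perceptron, shallow feedforward baselines), so forward and
backward passes are written out explicitly on numpy arrays.
"""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive-moment optimizer over a list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Inverted-dropout mask; identity when rate == 0."""
    if rate <= 0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep) / keep


class BaselineMLP:
    """Three-layer perceptron f_b: two sigmoid hidden layers of n_hidden
    units and a scalar linear output; predicts the input-dependent part of
    the reward baseline."""

    def __init__(self, d: int, n_hidden: int, rng: np.random.Generator):
        self.W1 = glorot(rng, d, n_hidden)
        self.b1 = np.zeros(n_hidden)
        self.W2 = glorot(rng, n_hidden, n_hidden)
        self.b2 = np.zeros(n_hidden)
        self.W3 = glorot(rng, n_hidden, 1)
        self.b3 = np.zeros(1)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def forward(self, x: np.ndarray):
        h1 = sigmoid(x @ self.W1 + self.b1)
        h2 = sigmoid(h1 @ self.W2 + self.b2)
        out = (h2 @ self.W3 + self.b3)[:, 0]
        return out, (x, h1, h2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of sum(dout * output) w.r.t. params, matching .params order."""
        x, h1, h2 = cache
        d3 = dout[:, None]                      # (n,1)
        gW3 = h2.T @ d3
        gb3 = d3.sum(axis=0)
        d2 = (d3 @ self.W3.T) * h2 * (1 - h2)
        gW2 = h1.T @ d2
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ self.W2.T) * h1 * (1 - h1)
        gW1 = x.T @ d1
        gb1 = d1.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gW3, gb3]
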