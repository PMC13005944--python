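"""Neural comparison methods: a supervised DNN and an adversarial DANN.

Both expose the same fit/predict contract as the survival-reinforced
classifier so the evaluation harness treats all methods uniformly.  The
DNN is a single hidden layer + dropout + prediction layer trained with
cross-entropy.  DANN adds a domain classifier behind a gradient-reversal
connection: forward is the identity, backward multiplies the gradient
flowing from the domain head into the encoder by -grl_weight, pushing the
encoder toward cohort-invariant features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, dropout_mask, glorot, softmax
from .cohort_io import Cohort

__all__ = ["DnnConfig", "DannConfig", "DnnClassifier", "DannClassifier",
           "train_dnn", "train_dann"]


@dataclass
class DnnConfig:
    hidden_dim: int = 20
    dropout: float = 0.8
    lr: float = 0.01
    epochs: int = 2000
    seed: int = 0


@dataclass
class DannConfig:
    encoder_hidden: int = 20
    classifier_hidden: int = 10
    n_layers: int = 1          # 1 or 2, applied jointly to encoder and heads
    dropout: float = 0.0       # 0 or 0.3
    lr: float = 0.01
    momentum: float = 0.9
    grl_weight: float = 1.0    # final reversal scale; ramped in during training
    epochs: int = 2000
    seed: int = 0


def _onehot(labels: np.ndarray, k: int) -> np.ndarray:
    y = np.zeros((labels.size, k))
    y[np.arange(labels.size), np.asarray(labels, int) - 1] = 1.0
    return y


def _relu(x):
    return np.maximum(x, 0.0)


class _Stack:
    """Small relu feedforward stack with explicit backprop."""

    def __init__(self, dims: list[int], rng, final_linear: bool = True):
        self.W = [glorot(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        self.final_linear = final_linear

    @property
    def params(self):
        out = []
        for W, b in zip(self.W, self.b):
            out += [W, b]
        return out

    def forward(self, x):
        acts = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1 or not self.final_linear:
                h = _relu(h)
            acts.append(h)
        return h, acts

    def backward(self, acts, dout):
        grads = []
        d = dout
        for i in reversed(range(len(self.W))):
            if i < len(self.W) - 1 or not self.final_linear:
                d = d * (acts[i + 1] > 0)
            grads.insert(0, acts[i].T @ d)                      # gW
            grads.insert(1, d.sum(axis=0))                      # gb
            d = d @ self.W[i].T
        return grads, d


class DnnClassifier:
    """Hidden layer -> dropout -> prediction layer, cross-entropy trained."""

    def __init__(self, config: DnnConfig | None = None, k: int | None = None):
        self.config = config or DnnConfig()
        self.k = k

    def fit(self, source: Cohort, target: Cohort | None = None,
            validation: Cohort | None = None) -> "DnnClassifier":
        cfg = self.config
        if source.labels is None:
            raise ValueError("DNN training requires a labelled source cohort")
        X = source.x
        k = self.k or int(source.labels.max())
        self.k = k
        y = _onehot(source.labels, k)
        rng = np.random.default_rng(cfg.seed)
        n, d = X.shape
        self.W1 = glorot(rng, d, cfg.hidden_dim)
        self.b1 = np.zeros(cfg.hidden_dim)
        self.W2 = glorot(rng, cfg.hidden_dim, k)
        self.b2 = np.zeros(k)
        opt = Adam([self.W1, self.b1, self.W2, self.b2], lr=cfg.lr)
        for _ in range(cfg.epochs):
            h = _relu(X @ self.W1 + self.b1)
            h_d = h * dropout_mask(rng, h.shape, cfg.dropout)
            p = softmax(h_d @ self.W2 + self.b2)
            dlogits = (p - y) / n
            gW2 = h_d.T @ dlogits
            gb2 = dlogits.sum(axis=0)
            dh = (dlogits @ self.W2.T) * (h > 0)
            gW1 = X.T @ dh
            gb1 = dh.sum(axis=0)
            opt.step([gW1, gb1, gW2, gb2])
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        h = _relu(np.asarray(x, float) @ self.W1 + self.b1)
        return softmax(h @ self.W2 + self.b2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1) + 1


class DannClassifier:
    """Encoder + task head (source CE) + domain head (source-vs-target CE)
    joined by a gradient-reversal connection.

    Trained with momentum SGD and the usual reversal-weight ramp
    lambda(t) = grl_weight * (2 / (1 + exp(-10 t)) - 1), t = epoch
    fraction; adaptive per-parameter step sizes let the tiny domain head
    re-saturate instantly (its cross-entropy hits zero and all reversal
    pressure on the encoder vanishes), so a plain first-order optimizer is
    required for the adversarial game to reach domain confusion."""

    def __init__(self, config: DannConfig | None = None, k: int | None = None):
        self.config = config or DannConfig()
        self.k = k
        self.domain_history: list[float] = []

    def fit(self, source: Cohort, target: Cohort | None = None,
            validation: Cohort | None = None) -> "DannClassifier":
        cfg = self.config
        if source.labels is None:
            raise ValueError("DANN training requires a labelled source cohort")
        Xs = source.x
        k = self.k or int(source.labels.max())
        self.k = k
        y = _onehot(source.labels, k)
        Xt = target.x if target is not None else np.empty((0, Xs.shape[1]))
        rng = np.random.default_rng(cfg.seed)
        d = Xs.shape[1]
        enc_dims = ([d, cfg.encoder_hidden] if cfg.n_layers == 1
                    else [d, cfg.encoder_hidden, cfg.encoder_hidden])
        head_dims = lambda out: ([cfg.encoder_hidden, out] if cfg.n_layers == 1
                                 else [cfg.encoder_hidden, cfg.classifier_hidden, out])
        self.encoder = _Stack(enc_dims, rng, final_linear=False)
        self.task = _Stack(head_dims(k), rng)
        self.domain = _Stack(head_dims(2), rng)
        params = self.encoder.params + self.task.params + self.domain.params
        velocity = [np.zeros_like(p) for p in params]

        n_s, n_t = Xs.shape[0], Xt.shape[0]
        X_all = np.vstack([Xs, Xt])
        dom_y = _onehot(np.concatenate([np.ones(n_s), np.full(n_t, 2)]), 2)
        self.domain_history = []
        for epoch in range(cfg.epochs):
            progress = epoch / max(cfg.epochs - 1, 1)
            lam = cfg.grl_weight * (2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)
            z_all, enc_acts = self.encoder.forward(X_all)
            if cfg.dropout > 0:
                mask = dropout_mask(rng, z_all.shape, cfg.dropout)
                z_used = z_all * mask
            else:
                mask = None
                z_used = z_all
            z_s = z_used[:n_s]

            t_logits, t_acts = self.task.forward(z_s)
            p_task = softmax(t_logits)
            d_t = (p_task - y) / n_s
            t_grads, dz_task = self.task.backward(t_acts, d_t)

            dz_enc = np.zeros_like(z_all)
            dz_enc[:n_s] += dz_task
            if n_t > 0 and cfg.grl_weight != 0:
                d_logits, d_acts = self.domain.forward(z_used)
                p_dom = softmax(d_logits)
                self.domain_history.append(
                    float((np.argmax(p_dom, 1) == np.argmax(dom_y, 1)).mean()))
                d_d = (p_dom - dom_y) / (n_s + n_t)
                d_grads, dz_dom = self.domain.backward(d_acts, d_d)
                # gradient reversal: domain head descends its own loss, the
                # encoder ascends it
                dz_enc += -lam * dz_dom
            else:
                d_grads = [np.zeros_like(p) for p in self.domain.params]
            if mask is not None:
                dz_enc = dz_enc * mask
            e_grads, _ = self.encoder.backward(enc_acts, dz_enc)
            for p, g, v in zip(params, e_grads + t_grads + d_grads, velocity):
                v *= cfg.momentum
                v += g
                p -= cfg.lr * v
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z, _ = self.encoder.forward(np.asarray(x, float))
        logits, _ = self.task.forward(z)
        return softmax(logits)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1) + 1

    def predict_domain_proba(self, x: np.ndarray) -> np.ndarray:
        z, _ = self.encoder.forward(np.asarray(x, float))
        logits, _ = self.domain.forward(z)
        return softmax(logits)


def train_dnn(source: Cohort, cfg: DnnConfig | None = None) -> DnnClassifier:
    return DnnClassifier(cfg).fit(source)


def train_dann(source: Cohort, target: Cohort,
               cfg: DannConfig | None = None) -> DannClassifier:
    return DannClassifier(cfg).fit(source, target)
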