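"""Survival-reinforced patient stratification: model, losses, training loops.

The classifier is a single linear layer with softmax output (no bias):
logits l = Theta x.  On the labelled source cohort it is trained with
cross-entropy; on the unlabelled target cohort an on-policy policy
gradient (REINFORCE) pushes the predicted subtypes toward prognostic
separation, with the reward defined as the minimum pairwise restricted-
mean-survival-time gap between sampled subtype groups.  A learned reward
baseline (three-layer perceptron plus a trainable scalar) reduces the
variance of the policy gradient without changing its expectation.

Two ablations are provided: dropping the reward baseline (q = r), and
replacing the sampling-based policy gradient with a differentiable soft
relaxation of the RMST gap in which the Kaplan-Meier death and at-risk
counts accumulate subtype-membership probabilities instead of hard counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, BaselineMLP, dropout_mask, glorot, softmax
from .cohort_io import Cohort
from .survival_stats import rmst_by_group, rmst_gap_reward

__all__ = [
    "SrpsConfig",
    "SrpsModel",
    "TrainLog",
    "predict_proba",
    "predict_subtype",
    "sample_subtypes",
    "supervised_loss",
    "episode_reward",
    "advantage",
    "baseline_loss",
    "reinforce_loss",
    "train",
    "train_soft_ablation",
    "soft_delta_rmst",
    "SrpsClassifier",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

_EPS_LOG = 1e-12  # probability floor before logarithms


@dataclass
class SrpsConfig:
    """Training configuration.

    omega1/omega2 weight the supervised and reinforcement losses;
    l1_coeff penalizes ||Theta||_1; dropout_su / dropout_rl are input
    dropout rates for the two forward passes; n_hidden is the width of the
    baseline perceptron; lr_cls / lr_bl the Adam learning rates of the
    classifier and the baseline estimator.  With use_baseline=False the
    advantage reduces to the raw reward (ablation).
    """

    k: int = 2
    d: int = 20
    omega1: float = 0.1
    omega2: float = 1.0
    l1_coeff: float = 1e-5
    dropout_su: float = 0.0
    dropout_rl: float = 0.0
    n_hidden: int = 10
    lr_cls: float = 0.01
    lr_bl: float = 0.01
    episodes: int = 10_000
    early_stop: bool = False
    eval_every: int = 10
    t_restrict: float = 60.0
    endpoint: str = "OS"
    use_baseline: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.omega1 <= 1 and 0 <= self.omega2 <= 1):
            raise ValueError("omega1 and omega2 must lie in [0, 1]")
        if not (0 <= self.dropout_su < 1 and 0 <= self.dropout_rl < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.episodes <= 0:
            raise ValueError("episodes must be positive")


@dataclass
class SrpsModel:
    """Trained model: classifier weights Theta (k x d), baseline net, b_c."""

    theta: np.ndarray
    baseline: BaselineMLP | None
    b_c: np.ndarray
    config: SrpsConfig

    @property
    def k(self) -> int:
        return self.theta.shape[0]

    @property
    def d(self) -> int:
        return self.theta.shape[1]


@dataclass
class TrainLog:
    loss: np.ndarray
    l_ce: np.ndarray
    l_re: np.ndarray
    l_bl: np.ndarray
    reward: np.ndarray
    val_episodes: np.ndarray
    val_delta_rmst: np.ndarray
    best_episode: int = -1


def _init_model(cfg: SrpsConfig, rng: np.random.Generator) -> SrpsModel:
    theta = glorot(rng, cfg.d, cfg.k).T  # (k, d)
    baseline = BaselineMLP(cfg.d, cfg.n_hidden, rng) if cfg.use_baseline else None
    return SrpsModel(theta=theta, baseline=baseline, b_c=np.zeros(1), config=cfg)


def predict_proba(model: SrpsModel, x: np.ndarray, dropout: float = 0.0,
                  training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
    """Subtype probabilities p = softmax(Theta x); dropout only in training."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.d:
        raise ValueError(f"feature dimension {x.shape[1]} != model dimension {model.d}")
    if training and dropout > 0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        x = x * dropout_mask(rng, x.shape, dropout)
    return softmax(x @ model.theta.T)


def predict_subtype(model: SrpsModel, x: np.ndarray) -> np.ndarray:
    """Deterministic argmax prediction, subtypes 1..k; ties -> smaller index."""
    p = predict_proba(model, x)
    return np.argmax(p, axis=1) + 1


def sample_subtypes(probabilities: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per sample; returns a one-hot n x k matrix."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    cum = np.cumsum(p, axis=1)
    u = rng.random((p.shape[0], 1))
    idx = (u > cum).sum(axis=1)
    onehot = np.zeros_like(p)
    onehot[np.arange(p.shape[0]), idx] = 1.0
    return onehot


def supervised_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy -sum_s y(s) log p(s) over labelled samples."""
    if p.shape != y.shape:
        raise ValueError("probability and label matrices must have equal shape")
    logp = np.log(np.clip(p, _EPS_LOG, None))
    return float(-(y * logp).sum(axis=1).mean())


def episode_reward(yhat: np.ndarray, times, events, cfg: SrpsConfig) -> float:
    """Minimum pairwise RMST gap of the sampled subtype groups.

    If any subtype group is empty the reward is -t_restrict: the RMST of an
    empty group is undefined, and the strong penalty deters the degenerate
    all-one-subtype policy (logged when triggered).
    """
    groups = np.argmax(yhat, axis=1)
    tau = rmst_by_group(times, events, groups, cfg.k, cfg.t_restrict)
    if np.isnan(tau).any():
        log.debug("empty subtype group sampled; reward set to -t_restrict")
        return -cfg.t_restrict
    return rmst_gap_reward(tau)


def advantage(r: float, b_i: np.ndarray, b_c: float) -> np.ndarray:
    """Baseline-stabilized advantage q_i = r - b_i - b_c (no gradient flows
    through q into the classifier)."""
    return r - np.asarray(b_i, dtype=float) - b_c


def baseline_loss(r: float, b_i: np.ndarray, b_c: float) -> float:
    """L2 norm of the per-sample residual vector r - b_i - b_c."""
    return float(np.linalg.norm(r - np.asarray(b_i, dtype=float) - b_c))


def reinforce_loss(p: np.ndarray, yhat: np.ndarray, q: np.ndarray) -> float:
    """REINFORCE surrogate: -(1/N) sum_i q_i log p_i(yhat_i)."""
    logp = np.log(np.clip(p, _EPS_LOG, None))
    picked = (yhat * logp).sum(axis=1)
    return float(-(np.asarray(q) * picked).mean())


def _onehot_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    y = np.zeros((labels.size, k))
    y[np.arange(labels.size), labels - 1] = 1.0
    return y


def _check_pair(source: Cohort, target: Cohort | None) -> None:
    if source.labels is None:
        raise ValueError("source cohort must carry subtype labels")
    if target is not None and target.x.shape[1] != source.x.shape[1]:
        raise ValueError("source and target feature dimensions differ")
    if (target is not None
            and source.expr.protein_ids != target.expr.protein_ids):
        raise ValueError("source and target protein orderings differ")


def train(source: Cohort, target: Cohort | None, cfg: SrpsConfig,
          validation: Cohort | None = None) -> tuple[SrpsModel, TrainLog]:
    """Full-batch training of the survival-reinforced classifier.

    Per episode: (a) supervised cross-entropy on the labelled source batch
    (input dropout rho_su); (b) on the target batch (dropout rho_rl),
    sample subtypes from the predicted probabilities, compute the RMST-gap
    reward and the baseline-stabilized advantage, and form the REINFORCE
    loss; (c) one Adam step on omega1*l_CE + omega2*l_RE + l1*||Theta||_1;
    (d) a separate Adam step on the baseline L2 loss, so baseline errors
    never leak into Theta.  With early_stop and a validation cohort, the
    snapshot with the highest validation RMST gap (on deterministic argmax
    predictions) is returned instead of the final weights.
    """
    _check_pair(source, target if cfg.omega2 > 0 else None)
    rng = np.random.default_rng(cfg.seed)
    model = _init_model(cfg, rng)

    Xs = source.x
    y = _onehot_labels(source.labels, cfg.k)
    use_rl = cfg.omega2 > 0
    if use_rl:
        if target is None:
            raise ValueError("omega2 > 0 requires a target cohort with survival")
        Xt = target.x
        t_times, t_events = target.survival(cfg.endpoint)
        n_t = Xt.shape[0]
    if validation is not None:
        v_times, v_events = validation.survival(cfg.endpoint)

    bl_opt = None
    if use_rl and cfg.use_baseline:
        bl_params = model.baseline.params + [model.b_c]
        bl_opt = Adam(bl_params, lr=cfg.lr_bl)
    cls_opt = Adam([model.theta], lr=cfg.lr_cls)

    E = cfg.episodes
    logs = TrainLog(*(np.zeros(E) for _ in range(5)), np.array([]), np.array([]))
    val_eps, val_vals = [], []
    best_val, best_theta, best_ep = -np.inf, None, -1
    n_s = Xs.shape[0]

    for ep in range(E):
        # (a) supervised pass
        Xs_d = Xs * dropout_mask(rng, Xs.shape, cfg.dropout_su) if cfg.dropout_su > 0 else Xs
        ps = softmax(Xs_d @ model.theta.T)
        l_ce = supervised_loss(ps, y)
        dlogits_s = (ps - y) / n_s

        grad_theta = cfg.omega1 * (dlogits_s.T @ Xs_d)

        l_re = 0.0
        l_bl = 0.0
        r = np.nan
        if use_rl:
            # (b) reinforcement pass
            Xt_d = Xt * dropout_mask(rng, Xt.shape, cfg.dropout_rl) if cfg.dropout_rl > 0 else Xt
            pt = softmax(Xt_d @ model.theta.T)
            yhat = sample_subtypes(pt, rng)
            r = episode_reward(yhat, t_times, t_events, cfg)
            if cfg.use_baseline:
                b_i, bl_cache = model.baseline.forward(Xt)
            else:
                b_i = np.zeros(n_t)
            q = advantage(r, b_i, float(model.b_c[0]) if cfg.use_baseline else 0.0)
            l_re = reinforce_loss(pt, yhat, q)
            dlogits_t = (q[:, None] * (pt - yhat)) / n_t
            grad_theta += cfg.omega2 * (dlogits_t.T @ Xt_d)

            # (d) baseline update: l_BL = ||r - b_i - b_c||_2
            if cfg.use_baseline:
                l_bl = float(np.linalg.norm(q))
                if l_bl > 0:
                    dres = -q / l_bl
                    grads = model.baseline.backward(bl_cache, dres)
                    grads.append(np.array([dres.sum()]))
                    bl_opt.step(grads)

        grad_theta += cfg.l1_coeff * np.sign(model.theta)
        cls_opt.step([grad_theta])

        total = cfg.omega1 * l_ce + cfg.omega2 * l_re
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss at episode {ep}: l_CE={l_ce}, l_RE={l_re}")
        logs.loss[ep], logs.l_ce[ep], logs.l_re[ep] = total, l_ce, l_re
        logs.l_bl[ep], logs.reward[ep] = l_bl, r

        if validation is not None and (ep % cfg.eval_every == 0 or ep == E - 1):
            preds = predict_subtype(model, validation.x) - 1
            tau = rmst_by_group(v_times, v_events, preds, cfg.k, cfg.t_restrict)
            val_r = -cfg.t_restrict if np.isnan(tau).any() else rmst_gap_reward(tau)
            val_eps.append(ep)
            val_vals.append(val_r)
            if cfg.early_stop and val_r > best_val:
                best_val, best_theta, best_ep = val_r, model.theta.copy(), ep

    logs.val_episodes = np.array(val_eps)
    logs.val_delta_rmst = np.array(val_vals)
    if cfg.early_stop and best_theta is not None:
        model.theta = best_theta
        logs.best_episode = best_ep
    return model, logs


# ---------------------------------------------------------------------------
# soft-relaxation ablation: differentiable probability-weighted KM / RMST
# ---------------------------------------------------------------------------

class _SoftKMContext:
    """Precomputed time grid for probability-weighted KM curves.

    Death and at-risk counts at each distinct time accumulate the subtype-
    membership weight of each subject instead of hard counts, keeping the
    RMST differentiable in the weights.
    """

    def __init__(self, times, events, t_restrict: float):
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=float)
        self.order = np.argsort(t, kind="stable")
        ts = t[self.order]
        self.events_sorted = e[self.order]
        self.uniq, start = np.unique(ts, return_index=True)
        counts = np.diff(np.append(start, ts.size))
        self.start = start
        self.m_idx = np.repeat(np.arange(self.uniq.size), counts)
        cap = np.minimum(self.uniq, t_restrict)
        # seg[m] multiplies S_m = prod_{l<=m} f_l  (m = 1..M); seg0 multiplies S_0=1
        self.seg0 = cap[0] if self.uniq.size else t_restrict
        nxt = np.append(cap[1:], t_restrict)
        self.seg = nxt - cap
        self.n = t.size

    def value_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        """Soft RMST for weight vector w >= 0 (original sample order) and
        its gradient d tau / d w."""
        ws = w[self.order]
        d = np.add.reduceat(ws * self.events_sorted, self.start)
        # at-risk weight = suffix sums at each distinct time
        csum = np.cumsum(ws)
        total = csum[-1]
        before = np.concatenate(([0.0], csum))[self.start]
        n_at = np.maximum(total - before, 1e-12)
        f = np.clip(1.0 - d / n_at, 1e-12, 1.0)
        S = np.cumprod(f)
        tau = float(self.seg0 + np.sum(self.seg * S))
        # T_l = sum_{m >= l} seg_m S_m ;  G_l = T_l / f_l
        T = np.cumsum((self.seg * S)[::-1])[::-1]
        G = T / f
        dtau_dd = -G / n_at
        dtau_dn = G * d / (n_at ** 2)
        cum_dn = np.cumsum(dtau_dn)
        grad_sorted = self.events_sorted * dtau_dd[self.m_idx] + cum_dn[self.m_idx]
        grad = np.empty_like(w)
        grad[self.order] = grad_sorted
        return tau, grad


def soft_delta_rmst(p: np.ndarray, times, events, t_restrict: float = 60.0,
                    with_grad: bool = False):
    """Soft RMST gap: min pairwise gap of probability-weighted RMSTs.

    With hard one-hot rows this equals the hard RMST gap.  When
    ``with_grad`` is true, also returns d(gap)/dp (n x k), using the
    active (arg-min) pair's subgradient.
    """
    p = np.asarray(p, dtype=float)
    ctx = _SoftKMContext(times, events, t_restrict)
    k = p.shape[1]
    taus = np.empty(k)
    grads = []
    for s in range(k):
        taus[s], g = ctx.value_and_grad(p[:, s])
        grads.append(g)
    iu = np.stack(np.triu_indices(k, 1), axis=1)
    pair_gaps = np.array([taus[a] - taus[b] for a, b in iu])
    j = int(np.argmin(pair_gaps))
    gap = float(pair_gaps[j])
    if not with_grad:
        return gap
    a, b = iu[j]
    dgap = np.zeros_like(p)
    dgap[:, a] = grads[a]
    dgap[:, b] = -grads[b]
    return gap, dgap


def train_soft_ablation(source: Cohort, target: Cohort, cfg: SrpsConfig,
                        validation: Cohort | None = None) -> tuple[SrpsModel, TrainLog]:
    """Ablation replacing REINFORCE with a differentiable soft RMST gap.

    The loss omega1*l_CE - softDeltaRMST + l1*||Theta||_1 is minimized
    end-to-end; no sampling and no reward baseline are involved.
    """
    _check_pair(source, target)
    rng = np.random.default_rng(cfg.seed)
    model = _init_model(cfg, rng)
    Xs, Xt = source.x, target.x
    y = _onehot_labels(source.labels, cfg.k)
    t_times, t_events = target.survival(cfg.endpoint)
    if validation is not None:
        v_times, v_events = validation.survival(cfg.endpoint)
    opt = Adam([model.theta], lr=cfg.lr_cls)
    n_s, n_t = Xs.shape[0], Xt.shape[0]

    E = cfg.episodes
    logs = TrainLog(*(np.zeros(E) for _ in range(5)), np.array([]), np.array([]))
    val_eps, val_vals = [], []
    best_val, best_theta, best_ep = -np.inf, None, -1

    for ep in range(E):
        Xs_d = Xs * dropout_mask(rng, Xs.shape, cfg.dropout_su) if cfg.dropout_su > 0 else Xs
        ps = softmax(Xs_d @ model.theta.T)
        l_ce = supervised_loss(ps, y)
        dlogits_s = (ps - y) / n_s

        Xt_d = Xt * dropout_mask(rng, Xt.shape, cfg.dropout_rl) if cfg.dropout_rl > 0 else Xt
        pt = softmax(Xt_d @ model.theta.T)
        gap, dgap = soft_delta_rmst(pt, t_times, t_events, cfg.t_restrict, with_grad=True)
        # loss term is -gap; chain through the softmax rows
        dL_dp = -dgap
        inner = (dL_dp * pt).sum(axis=1, keepdims=True)
        dlogits_t = pt * (dL_dp - inner)

        grad_theta = (cfg.omega1 * (dlogits_s.T @ Xs_d)
                      + dlogits_t.T @ Xt_d
                      + cfg.l1_coeff * np.sign(model.theta))
        opt.step([grad_theta])

        total = cfg.omega1 * l_ce - gap
        if not np.isfinite(total):
            raise FloatingPointError(f"non-finite loss at episode {ep}")
        logs.loss[ep], logs.l_ce[ep], logs.reward[ep] = total, l_ce, gap

        if validation is not None and (ep % cfg.eval_every == 0 or ep == E - 1):
            preds = predict_subtype(model, validation.x) - 1
            tau = rmst_by_group(v_times, v_events, preds, cfg.k, cfg.t_restrict)
            val_r = -cfg.t_restrict if np.isnan(tau).any() else rmst_gap_reward(tau)
            val_eps.append(ep)
            val_vals.append(val_r)
            if cfg.early_stop and val_r > best_val:
                best_val, best_theta, best_ep = val_r, model.theta.copy(), ep

    logs.val_episodes = np.array(val_eps)
    logs.val_delta_rmst = np.array(val_vals)
    if cfg.early_stop and best_theta is not None:
        model.theta = best_theta
        logs.best_episode = best_ep
    return model, logs


# ---------------------------------------------------------------------------
# uniform classifier contract + serialization
# ---------------------------------------------------------------------------

class SrpsClassifier:
    """fit/predict wrapper sharing the harness's pluggable-classifier contract."""

    def __init__(self, config: SrpsConfig, variant: str = "full"):
        if variant not in ("full", "no_baseline", "soft"):
            raise ValueError(f"unknown variant {variant!r}")
        self.config = config
        self.variant = variant
        self.model: SrpsModel | None = None
        self.log: TrainLog | None = None

    def fit(self, source: Cohort, target: Cohort | None = None,
            validation: Cohort | None = None) -> "SrpsClassifier":
        cfg = self.config
        if self.variant == "no_baseline":
            cfg = replace_cfg(cfg, use_baseline=False)
        if self.variant == "soft":
            self.model, self.log = train_soft_ablation(source, target, cfg, validation)
        else:
            self.model, self.log = train(source, target, cfg, validation)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return predict_subtype(self.model, x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return predict_proba(self.model, x)


def replace_cfg(cfg: SrpsConfig, **kwargs) -> SrpsConfig:
    d = asdict(cfg)
    d.update(kwargs)
    return SrpsConfig(**d)


_FORMAT_VERSION = 1


def save_model(model: SrpsModel, path) -> None:
    """Serialize a model to a flat, version-stamped JSON file."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "theta": model.theta.tolist(),
        "b_c": model.b_c.tolist(),
    }
    if model.baseline is not None:
        for name, arr in zip(("W1", "b1", "W2", "b2", "W3", "b3"), model.baseline.params):
            payload[f"baseline_{name}"] = arr.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SrpsModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    cfg = SrpsConfig(**payload["config"])
    model = _init_model(cfg, np.random.default_rng(0))
    model.theta = np.asarray(payload["theta"], dtype=float)
    model.b_c = np.asarray(payload["b_c"], dtype=float)
    if model.baseline is not None and "baseline_W1" in payload:
        for name, param in zip(("W1", "b1", "W2", "b2", "W3", "b3"), model.baseline.params):
            param[...] = np.asarray(payload[f"baseline_{name}"], dtype=float)
    return model
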