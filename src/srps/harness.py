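"""Evaluation harness: cross-validation, grid search, accuracy maps,
ssGSEA subtype similarity, and interpretation-support reports.

The harness treats classifiers as pluggable objects with a
``fit(source, target, validation)`` / ``predict(x)`` / ``predict_proba(x)``
contract, so the survival-reinforced model, the neural baselines, and any
external predictor can be compared under identical repeated 5-fold
cross-validation.  Following the evaluation protocol, the five test folds
of one repeat are pooled before survival metrics are computed, so log-rank
scores and concordance indices are estimated on the full cohort.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .cohort_io import Cohort
from .survival_stats import concordance_index, logrank_score

__all__ = [
    "CvPlan",
    "HyperGrid",
    "EvalReport",
    "accuracy",
    "run_cv",
    "accuracy_map",
    "residual_map_test",
    "ssgsea_scores",
    "ssgsea_similarity",
    "univariate_cox_coefficient",
    "cox_coefficient_report",
    "optimal_split_survival",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CvPlan:
    """Repeated k-fold plan: per repeat, an even 5-way split rotating the
    test fold; the fold after the test fold serves as validation."""

    n_folds: int = 5
    n_repeats: int = 5
    seeds: tuple = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if len(self.seeds) < self.n_repeats:
            raise ValueError("need one seed per repeat")

    def assignment(self, n: int, repeat: int) -> np.ndarray:
        rng = np.random.default_rng(self.seeds[repeat])
        folds = np.empty(n, dtype=int)
        folds[rng.permutation(n)] = np.arange(n) % self.n_folds
        return folds


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter option sets searched per fold (144 combinations by
    default)."""

    n_hidden: tuple = (10, 100)
    omega1: tuple = (0.1, 0.01, 0.001)
    omega2: tuple = (1.0,)
    l1: tuple = (1e-5, 1e-4)
    dropout_su: tuple = (0.0, 0.3, 0.8)
    dropout_rl: tuple = (0.0, 0.2)
    early_stop: tuple = (True, False)

    def configs(self) -> list[dict]:
        keys = ("n_hidden", "omega1", "omega2", "l1_coeff",
                "dropout_su", "dropout_rl", "early_stop")
        opts = (self.n_hidden, self.omega1, self.omega2, self.l1,
                self.dropout_su, self.dropout_rl, self.early_stop)
        return [dict(zip(keys, combo)) for combo in itertools.product(*opts)]


@dataclass
class EvalReport:
    """Per-fold accuracies and per-repeat pooled survival metrics."""

    fold_rows: pd.DataFrame
    repeat_rows: pd.DataFrame
    models: list = field(default_factory=list)

    def summary(self) -> dict:
        out = {}
        for col in ("source_acc", "target_acc"):
            v = self.fold_rows[col].dropna()
            if len(v):
                out[col] = (float(v.mean()), float(v.std(ddof=0)))
        for col in self.repeat_rows.columns:
            if col == "repeat":
                continue
            v = self.repeat_rows[col].dropna()
            if len(v):
                out[col] = (float(v.mean()), float(v.std(ddof=0)))
        return out


def accuracy(pred, truth) -> float:
    """Fraction of correct predictions."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    return float((pred == truth).mean())


def _selection_score(clf, selection: str, source_val: Cohort, target_val: Cohort,
                     gene_sets, endpoint: str, allow_no_gene_sets: bool) -> float:
    if selection == "val_accuracy":
        # target labels exist on simulated data; fall back to source labels
        if target_val is not None and target_val.labels is not None:
            return accuracy(clf.predict(target_val.x), target_val.labels)
        return accuracy(clf.predict(source_val.x), source_val.labels)
    if selection == "logrank_ssgsea":
        t, e = target_val.survival(endpoint)
        preds = clf.predict(target_val.x)
        score = logrank_score(preds, t, e) if len(np.unique(preds)) > 1 else 0.0
        if gene_sets is None:
            if not allow_no_gene_sets:
                raise ValueError("selection='logrank_ssgsea' requires gene sets "
                                 "(or allow_no_gene_sets=True)")
            log.warning("no gene sets supplied: model selection uses the "
                        "log-rank score alone, without the ssGSEA >= 0.5 gate")
            return score
        src_pred = source_val.subset(np.arange(source_val.n_samples))
        src_pred.labels = clf.predict(source_val.x)
        tgt_pred = target_val.subset(np.arange(target_val.n_samples))
        tgt_pred.labels = preds
        sim = ssgsea_similarity(src_pred, tgt_pred, gene_sets)
        return score if sim >= 0.5 else -np.inf
    raise ValueError(f"unknown selection rule {selection!r}")


def run_cv(source: Cohort, target: Cohort, method, plan: CvPlan = CvPlan(),
           grid: list[dict] | HyperGrid | None = None,
           selection: str = "val_accuracy", gene_sets: dict | None = None,
           endpoint: str = "OS", allow_no_gene_sets: bool = True,
           keep_models: bool = False) -> EvalReport:
    """Repeated cross-validated evaluation of one method.

    ``method`` is a factory ``method(config, seed) -> classifier``;
    ``config`` is None when no grid is searched.  Per fold, every grid
    configuration is trained fresh and scored on the validation fold by
    the selection rule; the winner is evaluated on the test fold.  Per
    repeat, target-cohort test predictions from all folds are pooled
    before survival metrics are computed.
    """
    if isinstance(grid, HyperGrid):
        grid = grid.configs()
    configs: list = grid if grid else [None]
    fold_rows, repeat_rows = [], []
    models = []
    k_max = int(source.labels.max())
    t_all, e_all = target.survival(endpoint)

    for repeat in range(plan.n_repeats):
        folds_s = plan.assignment(source.n_samples, repeat)
        folds_t = plan.assignment(target.n_samples, repeat)
        pooled_pred = np.zeros(target.n_samples, dtype=int)
        pooled_pred_src = np.zeros(source.n_samples, dtype=int)
        pooled_score = np.zeros(target.n_samples)
        for f in range(plan.n_folds):
            v = (f + 1) % plan.n_folds
            tr_s = np.flatnonzero((folds_s != f) & (folds_s != v))
            tr_t = np.flatnonzero((folds_t != f) & (folds_t != v))
            src_tr, src_val = source.subset(tr_s), source.subset(np.flatnonzero(folds_s == v))
            tgt_tr, tgt_val = target.subset(tr_t), target.subset(np.flatnonzero(folds_t == v))
            src_te, tgt_te = source.subset(np.flatnonzero(folds_s == f)), \
                target.subset(np.flatnonzero(folds_t == f))

            best, best_score = None, -np.inf
            for config in configs:
                clf = method(config, plan.seeds[repeat])
                clf.fit(src_tr, tgt_tr, validation=tgt_val)
                if len(configs) == 1:
                    best = clf
                    break
                score = _selection_score(clf, selection, src_val, tgt_val,
                                         gene_sets, endpoint, allow_no_gene_sets)
                if score > best_score:
                    best, best_score = clf, score

            src_acc = accuracy(best.predict(src_te.x), src_te.labels)
            tgt_acc = (accuracy(best.predict(tgt_te.x), tgt_te.labels)
                       if tgt_te.labels is not None else np.nan)
            fold_rows.append({"repeat": repeat, "fold": f,
                              "source_acc": src_acc, "target_acc": tgt_acc})
            te_idx = np.flatnonzero(folds_t == f)
            pooled_pred[te_idx] = best.predict(tgt_te.x)
            pooled_pred_src[folds_s == f] = best.predict(src_te.x)
            proba = best.predict_proba(tgt_te.x)
            pooled_score[te_idx] = proba[:, 0] - proba[:, k_max - 1]
            if keep_models:
                models.append(best)

        lr = (logrank_score(pooled_pred, t_all, e_all)
              if len(np.unique(pooled_pred)) > 1 else 0.0)
        ci = concordance_index(pooled_score, t_all, e_all)
        row = {"repeat": repeat, "logrank": lr, "cindex": ci}
        if gene_sets is not None:
            src_pred = source.subset(np.arange(source.n_samples))
            src_pred.labels = pooled_pred_src
            tgt_pred = target.subset(np.arange(target.n_samples))
            tgt_pred.labels = pooled_pred
            row["ssgsea_similarity"] = ssgsea_similarity(src_pred, tgt_pred, gene_sets)
        repeat_rows.append(row)

    return EvalReport(pd.DataFrame(fold_rows), pd.DataFrame(repeat_rows), models)


# ---------------------------------------------------------------------------
# toy-grid accuracy maps
# ---------------------------------------------------------------------------

def accuracy_map(cells, strategy: str, make_classifier=None,
                 test_fraction: float = 0.2, seed: int = 0,
                 survival_threshold: float = 30.0) -> np.ndarray:
    """11 x 11 accuracy matrix over the toy grid (rows: swap ratios, columns:
    noise weights).

    Strategies: ``survival_threshold`` stratifies target-test subjects
    directly at the 30-month lifetime threshold (theoretical reference);
    ``feature_dnn`` and ``srps`` train ``make_classifier(seed)`` on the
    source (plus target-train survival for srps) and predict the held-out
    20% of the target.
    """
    if strategy not in ("survival_threshold", "feature_dnn", "srps"):
        raise ValueError(f"unknown strategy {strategy!r}")
    alphas = sorted({c.alpha for c in cells})
    swaps = sorted({c.swap for c in cells})
    grid = np.full((len(swaps), len(alphas)), np.nan)
    a_idx = {a: j for j, a in enumerate(alphas)}
    s_idx = {s: i for i, s in enumerate(swaps)}

    for cell in cells:
        tgt = cell.target
        n = tgt.n_samples
        # held-out split depends on the swap level only, so the
        # survival-threshold map is exactly constant along the noise axis
        rng = np.random.default_rng([seed, s_idx[cell.swap]])
        perm = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        tgt_te = tgt.subset(test_idx)
        truth = tgt_te.labels

        if strategy == "survival_threshold":
            t, _ = tgt_te.survival("OS")
            pred = np.where(t > survival_threshold, 1, 2)
        else:
            clf = make_classifier(seed)
            if strategy == "feature_dnn":
                clf.fit(cell.source)
            else:
                clf.fit(cell.source, tgt.subset(train_idx))
            pred = clf.predict(tgt_te.x)
        grid[s_idx[cell.swap], a_idx[cell.alpha]] = accuracy(pred, truth)
    return grid


def residual_map_test(map_a: np.ndarray, map_b: np.ndarray,
                      region: str = "all"):
    """Element-wise residual map_a - map_b and a one-sample, one-sided
    t-test of residuals > 0 over the stated region.

    ``upper_right`` is the 6 x 6 block with normalized noise scale >= 0.5
    (rightmost columns) and survival correlation >= 0.5 (lowest swap rows).
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal shape")
    residual = a - b
    if region == "all":
        vals = residual.ravel()
    elif region == "upper_right":
        n_r, n_c = residual.shape
        vals = residual[: (n_r + 1) // 2, n_c // 2:].ravel()
    else:
        raise ValueError(f"unknown region {region!r}")
    if np.allclose(vals.std(), 0) and np.allclose(vals.mean(), 0):
        return residual, 0.0, 0.5
    t_stat, p = stats.ttest_1samp(vals, 0.0, alternative="greater")
    return residual, float(t_stat), float(p)


# ---------------------------------------------------------------------------
# single-sample gene-set enrichment similarity
# ---------------------------------------------------------------------------

def ssgsea_scores(expr: pd.DataFrame, gene_sets: dict[str, list[str]],
                  weight: float = 0.25, min_overlap: int = 10) -> pd.DataFrame:
    """Single-sample enrichment scores (samples x gene sets).

    Rank-weighted running-sum statistic: per sample, genes are ordered by
    decreasing expression; the inside-set ECDF weights each set member by
    its expression rank to the power ``weight`` and the score is the sum
    of the inside-outside ECDF differences over all positions.  Gene sets
    with fewer than ``min_overlap`` measured genes are dropped.
    """
    genes = list(expr.columns)
    gene_pos = {g: i for i, g in enumerate(genes)}
    kept = {name: np.array([gene_pos[g] for g in members if g in gene_pos])
            for name, members in gene_sets.items()}
    kept = {name: idx for name, idx in kept.items() if idx.size >= min_overlap}
    if not kept:
        raise ValueError(f"no gene set has >= {min_overlap} overlapping genes")
    x = expr.to_numpy(dtype=float)
    n, d = x.shape
    out = np.zeros((n, len(kept)))
    set_masks = {name: np.isin(np.arange(d), idx) for name, idx in kept.items()}
    for i in range(n):
        order = np.argsort(-x[i], kind="stable")
        rank_stat = (d - pd.Series(x[i]).rank(method="average").to_numpy() + 1.0)
        rank_w = np.abs(rank_stat) ** weight
        for j, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[order]
            w = rank_w[order] * in_set
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / (d - in_set.sum())
            out[i, j] = np.sum(p_in - p_out)
    return pd.DataFrame(out, index=expr.index, columns=list(kept))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def ssgsea_similarity(source: Cohort, target: Cohort,
                      gene_sets: dict[str, list[str]],
                      min_overlap: int = 10) -> float:
    """Mean over subtypes of the cosine similarity between the cohorts'
    subtype-average enrichment-score vectors.

    Both cohorts must carry (predicted) subtype labels; a subtype absent
    from either cohort is skipped with a warning.
    """
    if source.labels is None or target.labels is None:
        raise ValueError("both cohorts need (predicted) subtype labels")
    s_scores = ssgsea_scores(source.expr.to_frame(), gene_sets, min_overlap=min_overlap)
    t_scores = ssgsea_scores(target.expr.to_frame(), gene_sets, min_overlap=min_overlap)
    subtypes = sorted(set(source.labels) | set(target.labels))
    sims = []
    for s in subtypes:
        in_s, in_t = source.labels == s, target.labels == s
        if not in_s.any() or not in_t.any():
            log.warning("subtype %d absent from one cohort; skipped in similarity", s)
            continue
        sims.append(_cosine(s_scores.to_numpy()[in_s].mean(axis=0),
                            t_scores.to_numpy()[in_t].mean(axis=0)))
    if not sims:
        raise ValueError("no subtype present in both cohorts")
    return float(np.mean(sims))


# ---------------------------------------------------------------------------
# interpretation support: univariate Cox fits and optimal-split survival
# ---------------------------------------------------------------------------

def univariate_cox_coefficient(values, times, events) -> float:
    """Coefficient of a univariate proportional-hazards fit on one
    (z-scored) covariate."""
    v = np.asarray(values, float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant covariate")
    df = pd.DataFrame({"x": (v - v.mean()) / sd,
                       "time": np.asarray(times, float),
                       "event": np.asarray(events, float)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.params_["x"])


def cox_coefficient_report(cohort: Cohort, delta, subtype: int,
                           endpoint: str = "OS") -> tuple[pd.DataFrame, float]:
    """Per-protein univariate Cox coefficients vs delta-weight scores.

    Returns the per-protein table (cox_coef, delta_weight) and the Pearson
    correlation between the two columns; proteins whose fit fails to
    converge are skipped with a log entry.
    """
    times, events = cohort.survival(endpoint)
    rows = []
    vals = delta.values[subtype - 1]
    pos = {p: i for i, p in enumerate(delta.proteins)}
    for j, protein in enumerate(cohort.expr.protein_ids):
        if protein not in pos:
            continue
        try:
            coef = univariate_cox_coefficient(cohort.expr.values[:, j], times, events)
        except Exception as exc:  # non-convergence or degenerate column
            log.info("skipping %s: %s", protein, exc)
            continue
        rows.append({"protein": protein, "cox_coef": coef,
                     "delta_weight": vals[pos[protein]]})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("fewer than two proteins with converged Cox fits")
    r = float(stats.pearsonr(table["cox_coef"], table["delta_weight"])[0])
    return table, r


def optimal_split_survival(expression, times, events,
                           min_group_frac: float = 0.1) -> tuple[float, float]:
    """Expression threshold maximizing log-rank separation.

    Grid-searches the observed values, excluding thresholds that leave
    fewer than ``min_group_frac`` of samples on either side; returns the
    maximizing threshold and its log-rank score.
    """
    v = np.asarray(expression, float)
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("degenerate expression vector")
    n = v.size
    best_thr, best_score = None, -np.inf
    for thr in uniq[:-1]:
        low = v <= thr
        n_low = int(low.sum())
        if n_low < min_group_frac * n or (n - n_low) < min_group_frac * n:
            continue
        score = logrank_score(low.astype(int), t, e)
        if score > best_score:
            best_thr, best_score = float(thr), score
    if best_thr is None:
        raise ValueError("no threshold satisfies the minimum group size")
    return best_thr, float(best_score)
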