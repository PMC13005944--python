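"""Synthetic cohort-pair generators.

Two families of inputs are produced:

* a toy grid — 121 source/target pairs over 11 additive batch-noise
  weights x 11 survival-swap ratios (2 subtypes, 20 features, uncensored
  survival split at a 30-month threshold), used for the accuracy-map
  experiments; and

* a benchmark pair — 1000 samples, 1000 features, 3 subtypes split over
  two batches, with Splatter-style gamma gene means, lognormal
  differential-expression and batch factors, Poisson-lognormal counts, and
  Weibull proportional-hazards survival (lambda = 0.005, gamma = 0.5),
  administratively censored.

Both generators derive every random draw from explicit seeds, and the toy
grid derives the survival/label stream from the swap index only, so that
survival-based stratification is exactly constant along the batch-noise
axis of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import ClinicalTable, Cohort, ExpressionMatrix

__all__ = [
    "ToyGridSpec",
    "BenchmarkSpec",
    "ToyCell",
    "make_toy_pair",
    "make_toy_grid",
    "make_benchmark_pair",
]


@dataclass(frozen=True)
class ToyGridSpec:
    """Configuration of the 11 x 11 toy grid.

    alpha scales additive feature noise between the cohorts (batch-effect
    axis, 0..4); swap is the fraction of subjects per subtype whose
    survival times are exchanged across subtypes (survival-correlation
    axis, 0..0.2).  Survival is uncensored: better-prognosis subjects live
    past ``survival_threshold`` months, the rest die before it.
    """

    n_per_cohort: int = 200
    d: int = 20
    noise_sd: float = 0.2
    alpha_grid: tuple = tuple(np.round(np.arange(0, 4.01, 0.4), 10))
    swap_grid: tuple = tuple(np.round(np.arange(0, 0.201, 0.02), 10))
    survival_threshold: float = 30.0
    t_max: float = 60.0
    class_sep: float = 0.4
    feature_sd: float = 0.15
    seed: int = 0


@dataclass(frozen=True)
class BenchmarkSpec:
    """Configuration of the two-batch, three-subtype benchmark generator.

    Expression is simulated on a log2-intensity scale: per-protein baseline
    levels, per-subtype differential-expression shifts, per-protein
    multiplicative batch factors (lognormal with location ``batch_loc`` and
    scale ``batch_scale`` in natural-log units; 0.01 = negligible batch
    effects, 2 = large) applied to the second batch, lognormal measurement
    noise, and a detection limit below which values are missing.
    subtype_log_hazard must increase so subtype 1 has the best prognosis.
    """

    n_samples: int = 1000
    n_features: int = 1000
    k: int = 3
    n_batches: int = 2
    batch_loc: float = 0.01
    batch_scale: float = 0.01
    weibull_lambda: float = 0.005
    weibull_gamma: float = 0.5
    subtype_log_hazard: tuple = (0.0, 1.0, 2.0)
    censor_admin_time: float = 60.0
    base_log2_mean: float = 3.0
    base_log2_sd: float = 2.0
    de_prob: float = 0.1
    de_loc: float = 0.5
    de_scale: float = 0.3
    noise_sd: float = 1.0
    detection_limit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.subtype_log_hazard) > 0):
            raise ValueError("subtype_log_hazard must be strictly increasing")


@dataclass
class ToyCell:
    alpha: float
    swap: float
    source: Cohort
    target: Cohort


def _grid_index(grid, value, name: str) -> int:
    grid = np.asarray(grid, dtype=float)
    j = int(np.argmin(np.abs(grid - value)))
    if abs(grid[j] - value) > 1e-9:
        raise ValueError(f"{name}={value} is not on the grid")
    return j


def _toy_cohort(x, labels, times, events, name) -> Cohort:
    n, d = x.shape
    ids = [f"{name}_{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(x, ids, [f"F{j + 1:02d}" for j in range(d)])
    clin = {"OS": ClinicalTable(ids, times, events, "OS")}
    return Cohort(expr, clin, labels, preprocessed=True, name=name)


def _toy_survival(labels, rng, spec: ToyGridSpec, swap: float):
    thr, tmax = spec.survival_threshold, spec.t_max
    n = labels.size
    times = np.where(labels == 1,
                     rng.uniform(thr, tmax, n) + 1e-9,  # strictly above threshold
                     rng.uniform(0.0, thr, n))
    # exchange survival times of floor(swap * n_subtype) random cross-subtype pairs
    idx1 = np.flatnonzero(labels == 1)
    idx2 = np.flatnonzero(labels == 2)
    n_swap = int(np.floor(swap * min(idx1.size, idx2.size)))
    if n_swap:
        pick1 = rng.choice(idx1, n_swap, replace=False)
        pick2 = rng.choice(idx2, n_swap, replace=False)
        times[pick1], times[pick2] = times[pick2].copy(), times[pick1].copy()
    return times, np.ones(n, dtype=int), n_swap


def make_toy_pair(spec: ToyGridSpec, alpha: float, swap: float) -> tuple[Cohort, Cohort]:
    """One toy source/target pair at the given noise weight and swap ratio.

    Source and target share the base features x_origin in [0,1]^d (two
    subtype-specific mean profiles, linearly separable at alpha = 0); the
    target additionally receives alpha * noise, where the noise has
    per-dimension means drawn once uniformly from [0,1] and SD 0.2.  The
    source keeps labels; the target carries uncensored survival (its true
    labels are retained for evaluation only).
    """
    ai = _grid_index(spec.alpha_grid, alpha, "alpha")
    si = _grid_index(spec.swap_grid, swap, "swap")
    # the data stream depends only on the swap index, so survival-based
    # accuracy is exactly constant along the batch-noise axis
    data_rng = np.random.default_rng([spec.seed, 7, si])
    noise_rng = np.random.default_rng([spec.seed, 11, ai, si])

    n, d = spec.n_per_cohort, spec.d
    half = d // 2
    labels = np.repeat([1, 2], [n - n // 2, n // 2])
    labels = data_rng.permutation(labels)
    lo = 0.5 - spec.class_sep / 2
    hi = 0.5 + spec.class_sep / 2
    means = np.where((labels == 1)[:, None],
                     np.concatenate([np.full(half, hi), np.full(d - half, lo)]),
                     np.concatenate([np.full(half, lo), np.full(d - half, hi)]))
    x_origin = np.clip(means + data_rng.normal(0, spec.feature_sd, (n, d)), 0.0, 1.0)

    noise_mu = noise_rng.uniform(0, 1, d)
    noise = noise_rng.normal(noise_mu, spec.noise_sd, (n, d))
    x_target = x_origin + alpha * noise

    s_times, s_events, _ = _toy_survival(labels, data_rng, spec, swap)
    t_times, t_events, _ = _toy_survival(labels, data_rng, spec, swap)
    source = _toy_cohort(x_origin, labels, s_times, s_events, "toy_source")
    target = _toy_cohort(x_target, labels, t_times, t_events, "toy_target")
    return source, target


def make_toy_grid(spec: ToyGridSpec) -> list[ToyCell]:
    """All 121 toy pairs (Cartesian product of the alpha and swap grids)."""
    cells = []
    for swap in spec.swap_grid:
        for alpha in spec.alpha_grid:
            src, tgt = make_toy_pair(spec, float(alpha), float(swap))
            cells.append(ToyCell(float(alpha), float(swap), src, tgt))
    return cells


def _log_factors(rng, n: int, loc: float, scale: float) -> np.ndarray:
    """Natural logs of per-protein multiplicative factors: |N(loc, scale)|
    with random sign, so half the proteins shift up and half down."""
    mag = np.abs(rng.normal(loc, scale, n))
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    return sign * mag


def weibull_ph_times(rng, log_hazard: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    """Inverse-CDF sampling from a Weibull proportional-hazards model.

    Baseline cumulative hazard H0(t) = lam * t**gamma; the subject-level
    hazard is scaled by exp(log_hazard)."""
    u = rng.uniform(size=log_hazard.size)
    return (-np.log(u) / (lam * np.exp(log_hazard))) ** (1.0 / gamma)


def make_benchmark_pair(spec: BenchmarkSpec) -> tuple[Cohort, Cohort]:
    """Benchmark source/target pair: batch 1 (labelled) vs batch 2 (survival).

    Log2 intensity = per-protein baseline + per-subtype DE shift
    (+ log2 batch factor for batch-2 samples) + Gaussian noise, i.e. all
    effects are multiplicative on the raw scale with lognormal noise.
    Values below the detection limit are recorded as missing.  Survival
    follows the Weibull proportional-hazards model with the configured
    per-subtype log-hazards, administratively censored.  Both cohorts keep
    true labels so simulated-data accuracy can be evaluated.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples, spec.n_features, spec.k
    subtype = rng.integers(0, k, n)            # 0-based internally
    batch = np.zeros(n, dtype=int)
    batch[rng.permutation(n)[: n // 2]] = 1

    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, d)
    de_shift = np.zeros((k, d))
    for s in range(k):
        is_de = rng.random(d) < spec.de_prob
        de_shift[s, is_de] = _log_factors(rng, int(is_de.sum()),
                                          spec.de_loc, spec.de_scale)
    # batch-2 proteins are scaled by lognormal(batch_loc, batch_scale)
    # factors (natural-log units, converted to the log2 intensity scale)
    batch_shift = _log_factors(rng, d, spec.batch_loc, spec.batch_scale) / np.log(2.0)

    log2_x = (base[None, :]
              + de_shift[subtype]
              + np.outer(batch.astype(float), batch_shift)
              + rng.normal(0.0, spec.noise_sd, (n, d)))
    values = np.where(log2_x >= spec.detection_limit, log2_x, np.nan)

    eta = np.asarray(spec.subtype_log_hazard)[subtype]
    t = weibull_ph_times(rng, eta, spec.weibull_lambda, spec.weibull_gamma)
    event = (t <= spec.censor_admin_time).astype(int)
    time = np.minimum(t, spec.censor_admin_time)

    cohorts = []
    for b, name in ((0, "bench_source"), (1, "bench_target")):
        mask = batch == b
        ids = [f"{name}_{i:04d}" for i in range(int(mask.sum()))]
        expr = ExpressionMatrix(values[mask], ids, [f"P{j + 1:04d}" for j in range(d)])
        clin = {"OS": ClinicalTable(ids, time[mask], event[mask], "OS")}
        cohorts.append(Cohort(expr, clin, subtype[mask] + 1, preprocessed=False, name=name))
    return cohorts[0], cohorts[1]
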