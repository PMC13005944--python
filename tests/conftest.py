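import numpy as np
import pytest

from srps.cohort_io import ClinicalTable, Cohort, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(x, labels=None, times=None, events=None, name="c",
                preprocessed=True, protein_ids=None):
    """Assemble a Cohort from plain arrays (test helper)."""
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    ids = [f"{name}{i}" for i in range(n)]
    proteins = protein_ids or [f"P{j}" for j in range(d)]
    expr = ExpressionMatrix(x, ids, proteins)
    clinical = {}
    if times is not None:
        clinical["OS"] = ClinicalTable(ids, np.asarray(times, float),
                                       np.asarray(events, int), "OS")
    return Cohort(expr, clinical, labels if labels is None else np.asarray(labels),
                  preprocessed=preprocessed, name=name)


@pytest.fixture
def small_labelled_pair(rng):
    """Tiny linearly separable source/target pair with survival."""
    n, d = 60, 6
    labels = np.repeat([1, 2], n // 2)
    # block-contrast means: separable through the origin (no bias term)
    block = np.concatenate([np.full(d // 2, 0.2), np.full(d - d // 2, -0.2)])
    mu = np.where((labels == 1)[:, None], block, -block)
    xs = mu + rng.normal(0, 0.1, (n, d))
    xt = mu + rng.normal(0, 0.1, (n, d))
    times = np.where(labels == 1, rng.uniform(31, 60, n), rng.uniform(1, 29, n))
    src = make_cohort(xs, labels=labels, times=times, events=np.ones(n), name="s")
    tgt = make_cohort(xt, labels=labels, times=times, events=np.ones(n), name="t")
    return src, tgt
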