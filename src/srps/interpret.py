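"""Subtype significance scoring of trained linear classifiers.

For a linear softmax classifier with weight matrix Theta (k subtypes x d
proteins), the contribution of protein i to calling subtype a is scored as

    delta_weight(a, i) = Theta(a, i) - mean_{b != a} Theta(b, i),

i.e. the protein's weight for that subtype minus the average of its
weights for the competitors.  Because proteins are z-scored upstream, the
scores are comparable across proteins.  Scores from repeated trainings are
averaged to damp the influence of random initialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DeltaWeightTable",
    "delta_weight",
    "aggregate_delta_weight",
    "rank_proteins",
    "ranking_stability",
    "write_delta_weight_tsv",
]

log = logging.getLogger(__name__)


@dataclass
class DeltaWeightTable:
    proteins: list[str]
    values: np.ndarray          # (k, d)
    n_models_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.proteins):
            raise ValueError("values must be k x len(proteins)")
        if not np.isfinite(self.values).all():
            raise ValueError("delta-weight values must be finite")


def delta_weight(theta: np.ndarray, proteins: list[str] | None = None) -> DeltaWeightTable:
    """Per-subtype, per-protein significance scores from classifier weights."""
    theta = np.asarray(theta, dtype=float)
    k, d = theta.shape
    if k < 2:
        raise ValueError("delta_weight requires at least two subtypes")
    col_sum = theta.sum(axis=0, keepdims=True)
    values = theta - (col_sum - theta) / (k - 1)
    if proteins is None:
        proteins = [f"P{i + 1}" for i in range(d)]
    return DeltaWeightTable(list(proteins), values)


def aggregate_delta_weight(tables: list[DeltaWeightTable]) -> DeltaWeightTable:
    """Element-wise mean over repeated models (e.g. 5 repeats x 5 folds)."""
    if not tables:
        raise ValueError("no tables to aggregate")
    first = tables[0]
    for t in tables[1:]:
        if t.proteins != first.proteins:
            raise ValueError("tables have mismatched protein sets/ordering")
    total = sum(t.n_models_averaged for t in tables)
    mean = sum(t.values * t.n_models_averaged for t in tables) / total
    return DeltaWeightTable(list(first.proteins), mean, total)


def rank_proteins(table: DeltaWeightTable, subtype: int, top_n: int = 30) -> list[str]:
    """Proteins in descending delta-weight order for one subtype (1-based).

    Ties are broken lexicographically by protein id (logged when hit)."""
    k, d = table.values.shape
    if not 1 <= subtype <= k:
        raise ValueError(f"subtype must lie in 1..{k}")
    if top_n > d:
        log.warning("top_n=%d exceeds %d proteins; clipped", top_n, d)
        top_n = d
    vals = table.values[subtype - 1]
    order = sorted(range(d), key=lambda i: (-vals[i], table.proteins[i]))
    if len(np.unique(vals)) < d:
        log.debug("delta-weight ties broken lexicographically by id")
    return [table.proteins[i] for i in order[:top_n]]


def ranking_stability(tables: list[DeltaWeightTable], subtype: int,
                      top_n: int = 10) -> np.ndarray:
    """Overlap fraction of each step's top-n with the final top-n.

    ``tables`` is a sequence over training checkpoints or growing model
    ensembles; the returned curve ends at 1 by construction."""
    if len(tables) < 2:
        raise ValueError("ranking_stability needs at least two tables")
    final = set(rank_proteins(tables[-1], subtype, top_n))
    return np.array([
        len(final & set(rank_proteins(t, subtype, top_n))) / len(final)
        for t in tables
    ])


def write_delta_weight_tsv(table: DeltaWeightTable, path) -> None:
    """Long-form TSV: protein, subtype, delta_weight, rank (within subtype)."""
    rows = []
    k, d = table.values.shape
    for s in range(1, k + 1):
        ranked = rank_proteins(table, s, top_n=d)
        rank_of = {p: r + 1 for r, p in enumerate(ranked)}
        for i, p in enumerate(table.proteins):
            rows.append((p, s, table.values[s - 1, i], rank_of[p]))
    pd.DataFrame(rows, columns=["protein", "subtype", "delta_weight", "rank"]) \
        .to_csv(path, sep="\t", index=False)
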