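"""Cohort data model, delimited-text I/O, and the proteomic preprocessing pipeline.

A :class:`Cohort` bundles an expression matrix (samples x proteins, missing
allowed), per-endpoint clinical tables (survival time in months, event
status), and optional subtype labels.  :func:`preprocess_pair` applies the
standard multi-cohort proteomics pipeline: quantile normalization, detection
filtering, zero imputation, per-protein z-scoring, and protein-set
intersection, leaving both cohorts with identically ordered features so a
single weight matrix can serve both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "Cohort",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_signature",
    "read_gmt",
    "preprocess_pair",
    "quantile_normalize",
]

log = logging.getLogger(__name__)

NA_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class ExpressionMatrix:
    """Real-valued samples x proteins matrix; NaN marks a missing measurement."""

    values: np.ndarray
    sample_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.protein_ids)} proteins"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.protein_ids)


@dataclass
class ClinicalTable:
    """Per-sample survival records for one endpoint (OS or RFS)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == self.time.size == self.event.size):
            raise ValueError("sample_ids, time and event must have equal length")
        if np.any(self.time < 0):
            raise ValueError("negative survival time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event status must be 0 or 1")


@dataclass
class Cohort:
    """One center's data: expression, clinical endpoints, optional subtype labels.

    ``labels`` are integers 1..k (smaller index = better prognosis).
    ``preprocessed`` records that the expression values are on the
    normalized scale expected by the models.
    """

    expr: ExpressionMatrix
    clinical: dict[str, ClinicalTable] = field(default_factory=dict)
    labels: np.ndarray | None = None
    preprocessed: bool = False
    name: str = "cohort"

    def __post_init__(self) -> None:
        sample_set = set(self.expr.sample_ids)
        for endpoint, table in self.clinical.items():
            if not set(table.sample_ids) <= sample_set:
                raise ValueError(f"clinical table {endpoint!r} has samples outside the cohort")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.expr.n_samples:
                raise ValueError("labels must cover all samples")

    @property
    def n_samples(self) -> int:
        return self.expr.n_samples

    @property
    def x(self) -> np.ndarray:
        return self.expr.values

    def survival(self, endpoint: str = "OS") -> tuple[np.ndarray, np.ndarray]:
        """(time, event) aligned to the expression sample order."""
        table = self.clinical[endpoint]
        idx = {s: i for i, s in enumerate(table.sample_ids)}
        order = [idx[s] for s in self.expr.sample_ids if s in idx]
        if len(order) != self.expr.n_samples:
            raise ValueError(f"endpoint {endpoint!r} does not cover all samples")
        return table.time[order], table.event[order]

    def subset(self, indices) -> "Cohort":
        """New cohort restricted to the given sample positions."""
        indices = np.asarray(indices)
        ids = [self.expr.sample_ids[i] for i in indices]
        expr = ExpressionMatrix(self.expr.values[indices], ids, list(self.expr.protein_ids))
        keep = set(ids)
        clinical = {}
        for endpoint, tab in self.clinical.items():
            mask = [s in keep for s in tab.sample_ids]
            clinical[endpoint] = ClinicalTable(
                [s for s, m in zip(tab.sample_ids, mask) if m],
                tab.time[mask], tab.event[mask], tab.endpoint,
            )
        labels = self.labels[indices] if self.labels is not None else None
        return Cohort(expr, clinical, labels, self.preprocessed, self.name)


def read_expression(path, orientation: str = "samples_in_rows",
                    sep: str | None = None, na_tokens=NA_TOKENS) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    The header row carries protein ids and the first column sample ids
    (or transposed, with ``orientation='proteins_in_rows'``).  Cells equal
    to one of ``na_tokens`` parse as missing, never as zero.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError("duplicate ids in header row")
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na_tokens),
                     keep_default_na=False)
    if orientation == "proteins_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    non_numeric = df.columns[[df[c].dtype == object for c in df.columns]]
    if len(non_numeric):
        raise ValueError(f"non-numeric cells in columns {list(non_numeric)[:5]}")
    return ExpressionMatrix(df.to_numpy(dtype=float),
                            [str(s) for s in df.index],
                            [str(p) for p in df.columns])


def write_expression(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def read_clinical(path, endpoint: str = "OS", sep: str | None = None) -> ClinicalTable:
    """Read a clinical table with columns sample_id, time, event.

    Rows with missing time are dropped (count logged); a negative time is
    an error; event is coerced to {0, 1}.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=list(NA_TOKENS), keep_default_na=False)
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    n_missing = int(df["time"].isna().sum())
    if n_missing:
        log.warning("dropping %d clinical rows with missing time", n_missing)
        df = df.dropna(subset=["time"])
    if (df["time"] < 0).any():
        raise ValueError("negative survival time in clinical table")
    event = pd.to_numeric(df["event"], errors="raise").astype(int)
    return ClinicalTable([str(s) for s in df["sample_id"]],
                         df["time"].to_numpy(), event.to_numpy(), endpoint)


def write_clinical(table: ClinicalTable, path, sep: str = "\t") -> None:
    pd.DataFrame({"sample_id": table.sample_ids, "time": table.time,
                  "event": table.event}).to_csv(path, sep=sep, index=False)


def read_signature(path) -> list[str]:
    """Plain-text signature list, one protein id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path) -> dict[str, list[str]]:
    """Standard GMT gene-set file: name, description, member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize sample rows; missing entries stay missing.

    Every sample's non-missing values are mapped onto a shared reference
    distribution (the mean of the per-sample order statistics, interpolated
    onto a common quantile grid); ties share the value of their averaged
    rank.  With no missing data all rows end up with identical sorted
    value vectors.
    """
    x = np.asarray(values, dtype=float)
    n, d = x.shape
    grid = (np.arange(d) + 0.5) / d
    # reference distribution on the common grid
    ref_rows = np.empty((n, d))
    for i in range(n):
        v = np.sort(x[i][~np.isnan(x[i])])
        if v.size == 0:
            raise ValueError(f"sample row {i} is entirely missing")
        q = (np.arange(v.size) + 0.5) / v.size
        ref_rows[i] = np.interp(grid, q, v)
    ref = ref_rows.mean(axis=0)
    out = np.full_like(x, np.nan)
    for i in range(n):
        mask = ~np.isnan(x[i])
        v = x[i][mask]
        # average ranks over ties so equal inputs map to equal outputs
        ranks = pd.Series(v).rank(method="average").to_numpy() - 1.0
        q = (ranks + 0.5) / v.size
        out[i, mask] = np.interp(q, grid, ref)
    return out


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD
    zero_sd = sd == 0
    if zero_sd.any():
        log.warning("%d constant protein columns set to zero after z-scoring", int(zero_sd.sum()))
    sd = np.where(zero_sd, 1.0, sd)
    z = (x - mu) / sd
    z[:, zero_sd] = 0.0
    return z


def _prep_single(cohort: Cohort, min_detection: float, zscore: bool) -> Cohort:
    x = quantile_normalize(cohort.expr.values)
    detected = (~np.isnan(x)).mean(axis=0) >= min_detection
    if not detected.any():
        raise ValueError(f"{cohort.name}: detection filter removed every protein")
    x = x[:, detected]
    proteins = [p for p, k in zip(cohort.expr.protein_ids, detected) if k]
    x = np.nan_to_num(x, nan=0.0)
    if zscore:
        x = _zscore_columns(x)
    expr = ExpressionMatrix(x, list(cohort.expr.sample_ids), proteins)
    return replace(cohort, expr=expr, preprocessed=True)


def _select_proteins(cohort: Cohort, proteins: list[str]) -> Cohort:
    pos = {p: i for i, p in enumerate(cohort.expr.protein_ids)}
    cols = [pos[p] for p in proteins]
    expr = ExpressionMatrix(cohort.expr.values[:, cols], list(cohort.expr.sample_ids), list(proteins))
    return replace(cohort, expr=expr)


def preprocess_pair(source: Cohort, target: Cohort,
                    signature: list[str] | None = None,
                    min_detection: float = 0.3,
                    zscore: str = "per_cohort") -> tuple[Cohort, Cohort]:
    """Joint preprocessing of a source/target cohort pair.

    Per cohort, in order: (1) quantile normalization across samples;
    (2) drop proteins detected (non-missing) in fewer than ``min_detection``
    of samples; (3) impute remaining missing values as zero; (4) z-score
    each protein column (population SD; constant columns become all-zero).
    Then (5) keep only proteins present in both cohorts, in the source's
    order, and (6) intersect with ``signature`` when given.  Both returned
    cohorts share an identical, identically ordered protein list.

    ``zscore='per_cohort'`` standardizes each cohort with its own column
    statistics (the multi-center pipeline).  ``zscore='pooled'`` uses
    column statistics pooled over both cohorts, preserving any systematic
    between-cohort shift in the standardized values — appropriate when the
    two cohorts are batches of one study and the shift itself is the
    object under test, as in the simulated benchmarks.
    """
    if zscore not in ("per_cohort", "pooled"):
        raise ValueError(f"unknown zscore mode {zscore!r}")
    per_cohort = zscore == "per_cohort"
    src = _prep_single(source, min_detection, per_cohort)
    tgt = _prep_single(target, min_detection, per_cohort)
    shared = [p for p in src.expr.protein_ids if p in set(tgt.expr.protein_ids)]
    if not shared:
        raise ValueError("common-protein intersection (step 5) emptied the feature set")
    if signature is not None:
        sig = set(signature)
        shared = [p for p in shared if p in sig]
        if not shared:
            raise ValueError("signature intersection (step 6) emptied the feature set")
    src, tgt = _select_proteins(src, shared), _select_proteins(tgt, shared)
    if not per_cohort:
        n_s = src.expr.n_samples
        pooled = np.vstack([src.expr.values, tgt.expr.values])
        pooled = _zscore_columns(pooled)
        src = replace(src, expr=ExpressionMatrix(
            pooled[:n_s], list(src.expr.sample_ids), list(src.expr.protein_ids)))
        tgt = replace(tgt, expr=ExpressionMatrix(
            pooled[n_s:], list(tgt.expr.sample_ids), list(tgt.expr.protein_ids)))
    return src, tgt
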