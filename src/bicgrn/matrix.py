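"""Expression-matrix data model, TSV IO and preprocessing.

The pipeline consumes a genes x conditions matrix of (log-ratio) expression
values with an explicit missing-value mask.  Preprocessing mirrors what is
routinely applied to two-colour microarray data before network inference:
KNN imputation of missing values, removal of flat / poorly measured genes,
and per-gene equal-frequency discretization for discrete Bayesian scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "ExpressionMatrix",
    "DiscreteMatrix",
    "PreprocessConfig",
    "ExpressionParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "knn_impute",
    "filter_genes",
    "discretize_quantile",
    "KNNImputer",
    "QuantileDiscretizer",
]

_MISSING_TOKENS = {"", "na", "nan"}


class ExpressionParseError(ValueError):
    """Raised when an expression TSV violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Real-valued genes x conditions matrix with a missing-value mask.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (rows).
    condition_ids : ordered unique condition identifiers (columns).
    values : float array of shape (n_genes, n_conditions); entries under the
        missing mask are ignored (stored as NaN by convention).
    missing_mask : boolean array, True where the measurement is missing.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition IDs")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite value outside the missing mask")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene ID {exc.args[0]!r}") from None

    def condition_index(self, conditions: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.condition_ids)}
        try:
            return np.array([lookup[c] for c in conditions], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown condition ID {exc.args[0]!r}") from None

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.condition_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )


@dataclass
class DiscreteMatrix:
    """Integer-state genes x conditions matrix (states in 0..levels-1)."""

    gene_ids: list[str]
    condition_ids: list[str]
    states: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        self.states = np.asarray(self.states, dtype=int)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.levels):
            raise ValueError("states outside 0..levels-1")
        if self.states.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("states shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape


@dataclass
class PreprocessConfig:
    """Preprocessing knobs: imputation neighbours, filtering, discretization."""

    knn_k: int = 10
    variance_threshold: float = 0.0
    max_missing_fraction: float = 1.0
    discretization_levels: int = 3

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.discretization_levels < 2:
            raise ValueError("discretization_levels must be >= 2")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.variance_threshold < 0:
            raise ValueError("variance_threshold must be >= 0")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Row 1 is a header whose first cell is arbitrary (conventionally "GENE")
    followed by condition IDs; each subsequent row is a gene ID followed by
    decimal values.  Empty cells, "NA" and "NaN" (case-insensitive) mark
    missing measurements.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ExpressionParseError(f"{path}: empty file")
        condition_ids = header.rstrip("\n").split("\t")[1:]
        n_cond = len(condition_ids)
        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[np.ndarray] = []
        mask_rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            gene = cells[0]
            if gene in seen:
                raise ExpressionParseError(f"duplicate gene ID {gene!r}")
            if len(cells) - 1 != n_cond:
                raise ExpressionParseError(
                    f"line {lineno}: expected {n_cond} values, got {len(cells) - 1}"
                )
            vals = np.empty(n_cond)
            miss = np.zeros(n_cond, dtype=bool)
            for j, cell in enumerate(cells[1:]):
                token = cell.strip()
                if token.lower() in _MISSING_TOKENS:
                    vals[j] = np.nan
                    miss[j] = True
                else:
                    try:
                        vals[j] = float(token)
                    except ValueError:
                        raise ExpressionParseError(
                            f"line {lineno}: cannot parse value {cell!r}"
                        ) from None
            seen.add(gene)
            gene_ids.append(gene)
            rows.append(vals)
            mask_rows.append(miss)
    values = np.array(rows) if rows else np.empty((0, n_cond))
    mask = np.array(mask_rows) if mask_rows else np.empty((0, n_cond), dtype=bool)
    return ExpressionMatrix(gene_ids, condition_ids, values, mask)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    """Write the TSV dialect accepted by :func:`read_expression_tsv` (missing -> "NA")."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("GENE\t" + "\t".join(m.condition_ids) + "\n")
        for i, gene in enumerate(m.gene_ids):
            cells = [
                "NA" if m.missing_mask[i, j] else repr(float(m.values[i, j]))
                for j in range(len(m.condition_ids))
            ]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

class KNNImputer(BaseEstimator):
    """Gene-wise K-nearest-neighbour imputation of missing expression values.

    For each missing cell, the k gene rows nearest in Euclidean distance
    (computed over mutually observed conditions and scaled by the number of
    shared conditions) that have an observed value in the target condition
    contribute the unweighted mean of their values there.

    Parameters
    ----------
    k : number of neighbour rows averaged per imputed cell (default 10).
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, m: ExpressionMatrix, y=None) -> "KNNImputer":
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.matrix_ = m
        return self

    def transform(self, m: ExpressionMatrix | None = None) -> ExpressionMatrix:
        m = self.matrix_ if m is None else m
        return self._impute(m)

    def fit_transform(self, m: ExpressionMatrix, y=None) -> ExpressionMatrix:
        return self.fit(m).transform()

    def _impute(self, m: ExpressionMatrix) -> ExpressionMatrix:
        values = m.values.copy()
        mask = m.missing_mask
        if not mask.any():
            return m.copy()
        observed = ~mask
        n_obs_per_gene = observed.sum(axis=1)
        for i in np.flatnonzero(n_obs_per_gene == 0):
            raise ValueError(f"gene {m.gene_ids[i]!r} has no observed values")

        X = np.where(mask, 0.0, values)
        n_genes = m.shape[0]
        # pairwise mean squared difference over shared observed conditions
        shared = observed.astype(float) @ observed.astype(float).T
        sq = X**2
        cross = X @ X.T
        ssq_i = sq @ observed.astype(float).T  # sum_j obs x_i^2 over shared
        dist2 = ssq_i + ssq_i.T - 2 * cross
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_dist2 = np.where(shared > 0, dist2 / shared, np.inf)
        np.fill_diagonal(mean_dist2, np.inf)

        warned = False
        out = values.copy()
        for i, j in zip(*np.nonzero(mask)):
            eligible = np.flatnonzero(observed[:, j] & np.isfinite(mean_dist2[i]))
            if eligible.size == 0:
                raise ValueError(
                    f"cannot impute gene {m.gene_ids[i]!r} at condition "
                    f"{m.condition_ids[j]!r}: no eligible neighbours"
                )
            if eligible.size < self.k and not warned:
                warnings.warn(
                    f"fewer than k={self.k} eligible neighbours; using all",
                    stacklevel=2,
                )
                warned = True
            order = eligible[np.argsort(mean_dist2[i, eligible], kind="stable")]
            nbrs = order[: self.k]
            out[i, j] = values[nbrs, j].mean()
        return ExpressionMatrix(
            list(m.gene_ids),
            list(m.condition_ids),
            out,
            np.zeros_like(mask),
        )


def knn_impute(m: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing values; see :class:`KNNImputer`."""
    return KNNImputer(k=k).fit_transform(m)


# ---------------------------------------------------------------------------
# Gene filtration
# ---------------------------------------------------------------------------

def filter_genes(m: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Drop genes with little variation or too many missing measurements.

    A gene is retained iff its observed-value variance is >= cfg.variance_threshold
    and its missing fraction is <= cfg.max_missing_fraction.  Gene order and the
    condition set are preserved.
    """
    keep: list[int] = []
    n_cond = len(m.condition_ids)
    for i in range(m.shape[0]):
        obs = m.values[i, ~m.missing_mask[i]]
        var = float(np.var(obs)) if obs.size else 0.0
        miss_frac = float(m.missing_mask[i].sum()) / n_cond if n_cond else 0.0
        if var >= cfg.variance_threshold and miss_frac <= cfg.max_missing_fraction:
            keep.append(i)
    if not keep:
        raise ValueError(
            "all genes removed by filtering; reduce variance_threshold or "
            "raise max_missing_fraction"
        )
    idx = np.array(keep, dtype=int)
    return ExpressionMatrix(
        [m.gene_ids[i] for i in keep],
        list(m.condition_ids),
        m.values[idx],
        m.missing_mask[idx],
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

class QuantileDiscretizer(BaseEstimator):
    """Per-gene equal-frequency discretization into ``levels`` states.

    Each gene's values are ranked and cut into bins of (near) equal size;
    tied values all take the lower bin, so a constant gene maps to state 0.
    The output depends only on within-gene value order, making it invariant
    to strictly monotone per-gene transforms.
    """

    def __init__(self, levels: int = 3):
        self.levels = levels

    def fit(self, m: ExpressionMatrix, y=None) -> "QuantileDiscretizer":
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        self.matrix_ = m
        return self

    def transform(self, m: ExpressionMatrix | None = None) -> DiscreteMatrix:
        m = self.matrix_ if m is None else m
        if m.missing_mask.any():
            raise ValueError("matrix has missing values; run knn_impute first")
        states = np.empty(m.shape, dtype=int)
        n = m.shape[1]
        for i in range(m.shape[0]):
            states[i] = _equal_frequency_bins(m.values[i], self.levels, n)
        return DiscreteMatrix(list(m.gene_ids), list(m.condition_ids), states, self.levels)

    def fit_transform(self, m: ExpressionMatrix, y=None) -> DiscreteMatrix:
        return self.fit(m).transform()


def _equal_frequency_bins(row: np.ndarray, levels: int, n: int) -> np.ndarray:
    order = np.argsort(row, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    # min-rank over ties so equal values share the lower bin
    sorted_vals = row[order]
    min_rank_sorted = np.arange(n)
    for t in range(1, n):
        if sorted_vals[t] == sorted_vals[t - 1]:
            min_rank_sorted[t] = min_rank_sorted[t - 1]
    min_rank = np.empty(n, dtype=int)
    min_rank[order] = min_rank_sorted
    return min_rank * levels // n


def discretize_quantile(m: ExpressionMatrix, levels: int = 3) -> DiscreteMatrix:
    """Discretize per gene into equal-frequency bins; see :class:`QuantileDiscretizer`."""
    return QuantileDiscretizer(levels=levels).fit_transform(m)
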