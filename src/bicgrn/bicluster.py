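"""Biclustering algorithms and bicluster bookkeeping.

Implements the three bicluster families used for network construction —
Cheng–Church delta-biclusters (mean-squared-residue minimization), the
Iterative Signature Algorithm (ISA), and Order-Preserving SubMatrices
(OPSM) — plus k-means gene clusters re-expressed as biclusters spanning all
conditions.  External biclustering results can be imported from a simple
text interchange format so algorithms outside this package can join the
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

__all__ = [
    "Bicluster",
    "BiclusterSet",
    "BiclusterStats",
    "CCParams",
    "ISAParams",
    "OPSMParams",
    "KMeansParams",
    "ChengChurch",
    "IterativeSignature",
    "OPSM",
    "KMeansBiclustering",
    "mean_squared_residue",
    "cc_bicluster",
    "isa_bicluster",
    "opsm_bicluster",
    "kmeans_as_biclusters",
    "import_external_biclusters",
    "write_biclusters",
    "bicluster_stats",
]


@dataclass
class Bicluster:
    """A gene subset x condition subset with the algorithm that produced it."""

    genes: list[str]
    conditions: list[str]
    source: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.conditions = list(self.conditions)
        if not self.genes or not self.conditions:
            raise ValueError("bicluster must have at least one gene and one condition")

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)

    @property
    def condition_set(self) -> frozenset:
        return frozenset(self.conditions)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genes), len(self.conditions))


@dataclass
class BiclusterSet:
    biclusters: list[Bicluster]
    matrix_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.biclusters = list(self.biclusters)
        if self.matrix_shape[0] <= 0 or self.matrix_shape[1] <= 0:
            raise ValueError("matrix_shape must be positive")

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, i):
        return self.biclusters[i]


@dataclass
class CCParams:
    """Cheng–Church parameters: delta (max accepted MSR), alpha (deletion
    scaling factor), number of biclusters, and the masking RNG seed."""

    delta: float = 0.5
    alpha: float = 1.2
    n_biclusters: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


@dataclass
class ISAParams:
    """ISA parameters: gene/condition z thresholds and the number of random seeds."""

    t_g: float = 2.0
    t_c: float = 2.0
    n_seeds: int = 500
    rng_seed: int = 0
    max_iter: int = 50
    dedup_jaccard: float = 0.9
    seed_size: int = 5
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not 0 < self.dedup_jaccard <= 1:
            raise ValueError("dedup_jaccard must be in (0, 1]")
        if self.direction not in ("up", "updown"):
            raise ValueError("direction must be 'up' or 'updown'")


@dataclass
class OPSMParams:
    """OPSM parameters: number of partial models carried per size."""

    l_models: int = 100
    min_columns: int = 2

    def __post_init__(self) -> None:
        if self.l_models < 1:
            raise ValueError("l_models must be >= 1")
        if self.min_columns < 2:
            raise ValueError("min_columns must be >= 2")


@dataclass
class KMeansParams:
    """k-means parameters (clusters reported as biclusters over all conditions)."""

    n_clusters: int = 100
    n_iter: int = 100
    n_replicates: int = 10
    distance: str = "euclidean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.distance != "euclidean":
            raise ValueError("only euclidean distance is supported")


# ---------------------------------------------------------------------------
# Mean squared residue
# ---------------------------------------------------------------------------

def _submatrix(m: ExpressionMatrix, b: Bicluster) -> np.ndarray:
    gi = m.gene_index(b.genes)
    ci = m.condition_index(b.conditions)
    if m.missing_mask[np.ix_(gi, ci)].any():
        raise ValueError("missing value inside bicluster submatrix")
    return m.values[np.ix_(gi, ci)]


def _msr(sub: np.ndarray) -> float:
    row_means = sub.mean(axis=1, keepdims=True)
    col_means = sub.mean(axis=0, keepdims=True)
    overall = sub.mean()
    residue = sub - row_means - col_means + overall
    return float(np.mean(residue**2))


def mean_squared_residue(m: ExpressionMatrix, b: Bicluster) -> float:
    """Cheng–Church coherence score of a bicluster.

    H(I,J) = (1/|I||J|) sum_{i,j} (x_ij - x_iJ - x_Ij + x_IJ)^2 where x_iJ,
    x_Ij, x_IJ are row, column and overall bicluster means.  Zero for any
    submatrix of the form x_ij = r_i + c_j (constant and purely additive
    patterns).
    """
    return _msr(_submatrix(m, b))


# ---------------------------------------------------------------------------
# Cheng–Church
# ---------------------------------------------------------------------------

class ChengChurch(BaseEstimator):
    """Cheng–Church delta-biclustering.

    Repeatedly extracts a submatrix with mean squared residue <= delta via
    multiple-node deletion (drop rows/columns whose mean residue exceeds
    alpha x current MSR), single-node deletion, and node addition; the
    extracted cells are then masked with uniform random values over the
    matrix's observed range so subsequent biclusters differ.
    """

    def __init__(self, delta: float = 0.5, alpha: float = 1.2,
                 n_biclusters: int = 100, rng_seed: int = 0):
        self.delta = delta
        self.alpha = alpha
        self.n_biclusters = n_biclusters
        self.rng_seed = rng_seed

    def fit(self, m: ExpressionMatrix, y=None) -> "ChengChurch":
        p = CCParams(self.delta, self.alpha, self.n_biclusters, self.rng_seed)
        if m.missing_mask.any():
            raise ValueError("matrix has missing values; impute first")
        if m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("matrix must be at least 2x2")
        rng = np.random.default_rng(p.rng_seed)
        A = m.values.copy()
        lo, hi = float(A.min()), float(A.max())
        found: list[Bicluster] = []
        for _ in range(p.n_biclusters):
            rows, cols = self._extract(A, p)
            if rows.size == 0 or cols.size == 0:
                break
            sub = A[np.ix_(rows, cols)]
            found.append(
                Bicluster(
                    [m.gene_ids[i] for i in rows],
                    [m.condition_ids[j] for j in cols],
                    source="CC",
                    score=_msr(sub),
                )
            )
            A[np.ix_(rows, cols)] = rng.uniform(lo, hi, size=sub.shape)
        self.biclusters_ = BiclusterSet(found, m.shape)
        return self

    # -- single bicluster extraction --------------------------------------
    def _extract(self, A: np.ndarray, p: CCParams) -> tuple[np.ndarray, np.ndarray]:
        rows = np.arange(A.shape[0])
        cols = np.arange(A.shape[1])

        def residues(r, c):
            sub = A[np.ix_(r, c)]
            rm = sub.mean(axis=1, keepdims=True)
            cm = sub.mean(axis=0, keepdims=True)
            ov = sub.mean()
            res2 = (sub - rm - cm + ov) ** 2
            return res2.mean(), res2.mean(axis=1), res2.mean(axis=0)

        # multiple node deletion
        while rows.size > 2 and cols.size > 2:
            H, row_res, col_res = residues(rows, cols)
            if H <= p.delta:
                break
            keep_r = row_res <= p.alpha * H
            if keep_r.sum() >= 2 and not keep_r.all():
                rows = rows[keep_r]
            removed_rows = not keep_r.all() and keep_r.sum() >= 2
            H, row_res, col_res = residues(rows, cols)
            if H <= p.delta:
                break
            keep_c = col_res <= p.alpha * H
            removed_cols = False
            if keep_c.sum() >= 2 and not keep_c.all():
                cols = cols[keep_c]
                removed_cols = True
            if not removed_rows and not removed_cols:
                break

        # single node deletion (a 1xk or kx1 submatrix has zero residue,
        # so this always terminates with MSR <= delta)
        while True:
            H, row_res, col_res = residues(rows, cols)
            if H <= p.delta or rows.size <= 1 or cols.size <= 1:
                break
            ri = int(np.argmax(row_res))
            ci = int(np.argmax(col_res))
            if row_res[ri] >= col_res[ci]:
                rows = np.delete(rows, ri)
            else:
                cols = np.delete(cols, ci)

        # node addition
        changed = True
        while changed:
            changed = False
            H, _, _ = residues(rows, cols)
            # columns first
            other_c = np.setdiff1d(np.arange(A.shape[1]), cols)
            if other_c.size:
                sub = A[np.ix_(rows, cols)]
                rm = sub.mean(axis=1)
                ov = sub.mean()
                cand = A[np.ix_(rows, other_c)]
                cand_cm = cand.mean(axis=0)
                d = ((cand - rm[:, None] - cand_cm[None, :] + ov) ** 2).mean(axis=0)
                add = other_c[d <= H]
                if add.size:
                    cols = np.sort(np.concatenate([cols, add]))
                    changed = True
                    H, _, _ = residues(rows, cols)
            other_r = np.setdiff1d(np.arange(A.shape[0]), rows)
            if other_r.size:
                sub = A[np.ix_(rows, cols)]
                cm = sub.mean(axis=0)
                ov = sub.mean()
                cand = A[np.ix_(other_r, cols)]
                cand_rm = cand.mean(axis=1)
                d = ((cand - cand_rm[:, None] - cm[None, :] + ov) ** 2).mean(axis=1)
                add = other_r[d <= H]
                if add.size:
                    rows = np.sort(np.concatenate([rows, add]))
                    changed = True

        # guard: mean shifts during addition can nudge the score past delta
        while True:
            H, row_res, col_res = residues(rows, cols)
            if H <= p.delta or rows.size <= 1 or cols.size <= 1:
                break
            ri = int(np.argmax(row_res))
            ci = int(np.argmax(col_res))
            if row_res[ri] >= col_res[ci]:
                rows = np.delete(rows, ri)
            else:
                cols = np.delete(cols, ci)
        return rows, cols


def cc_bicluster(m: ExpressionMatrix, p: CCParams) -> BiclusterSet:
    """Run Cheng–Church biclustering; see :class:`ChengChurch`."""
    if p.n_biclusters == 0:
        if m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("matrix must be at least 2x2")
        return BiclusterSet([], m.shape)
    est = ChengChurch(p.delta, p.alpha, p.n_biclusters, p.rng_seed)
    return est.fit(m).biclusters_


# ---------------------------------------------------------------------------
# ISA
# ---------------------------------------------------------------------------

class IterativeSignature(BaseEstimator):
    """Iterative Signature Algorithm.

    From each random gene seed, alternates: score conditions by the mean of
    row-standardized expression over the current gene set, keeping those
    with |z| >= t_c; then score genes by the mean of column-standardized
    expression over the kept conditions, keeping |z| >= t_g.  z is the score
    divided by its standard error (score x sqrt(set size), since the
    standardized entries have unit variance).  Iteration stops at a fixed
    point of the gene set; converged modules are deduplicated by gene-set
    Jaccard similarity.

    ``direction="up"`` (default) keeps only positively scoring genes and
    conditions — the up-regulation signature that matches co-expressed
    modules such as stress responses.  ``direction="updown"`` thresholds
    |z| on both sides; the module's complement then tends to enter on the
    negative side (the module shifts the column means every other gene is
    standardized against), diluting recovered modules.
    """

    def __init__(self, t_g: float = 2.0, t_c: float = 2.0, n_seeds: int = 500,
                 rng_seed: int = 0, max_iter: int = 50,
                 dedup_jaccard: float = 0.9, seed_size: int = 5,
                 direction: str = "up"):
        self.t_g = t_g
        self.t_c = t_c
        self.n_seeds = n_seeds
        self.rng_seed = rng_seed
        self.max_iter = max_iter
        self.dedup_jaccard = dedup_jaccard
        self.seed_size = seed_size
        self.direction = direction

    def fit(self, m: ExpressionMatrix, y=None) -> "IterativeSignature":
        if self.t_g <= 0 or self.t_c <= 0:
            raise ValueError("thresholds t_g and t_c must be positive")
        if m.missing_mask.any():
            raise ValueError("matrix has missing values; impute first")
        p = ISAParams(self.t_g, self.t_c, self.n_seeds, self.rng_seed,
                      self.max_iter, self.dedup_jaccard, self.seed_size,
                      self.direction)
        X = m.values
        n_genes, n_cond = X.shape
        Xr = _standardize(X, axis=1)   # per gene, for condition scoring
        Xc = _standardize(X, axis=0)   # per condition, for gene scoring
        rng = np.random.default_rng(p.rng_seed)

        modules: list[tuple[np.ndarray, np.ndarray]] = []
        size = min(p.seed_size, n_genes)
        for _ in range(p.n_seeds):
            genes = np.sort(rng.choice(n_genes, size=size, replace=False))
            conds = np.array([], dtype=int)
            converged = False
            for _ in range(p.max_iter):
                conds = self._threshold(Xr[genes].mean(axis=0), len(genes), p.t_c)
                if conds.size == 0:
                    break
                new_genes = self._threshold(
                    Xc[:, conds].mean(axis=1), conds.size, p.t_g
                )
                if new_genes.size == 0:
                    break
                if np.array_equal(new_genes, genes):
                    converged = True
                    break
                genes = new_genes
            if converged and genes.size and conds.size:
                modules.append((genes, conds))

        kept: list[tuple[np.ndarray, np.ndarray]] = []
        for genes, conds in modules:
            gset = set(genes.tolist())
            dup = any(
                _jaccard(gset, set(g2.tolist())) >= p.dedup_jaccard
                for g2, _ in kept
            )
            if not dup:
                kept.append((genes, conds))

        self.biclusters_ = BiclusterSet(
            [
                Bicluster(
                    [m.gene_ids[i] for i in genes],
                    [m.condition_ids[j] for j in conds],
                    source="ISA",
                )
                for genes, conds in kept
            ],
            m.shape,
        )
        return self

    def _threshold(self, scores: np.ndarray, set_size: int, t: float) -> np.ndarray:
        z = scores * np.sqrt(set_size)
        if self.direction == "up":
            return np.flatnonzero(z >= t)
        return np.flatnonzero(np.abs(z) >= t)

    def signature_step(self, m: ExpressionMatrix, genes: list[str]
                       ) -> tuple[list[str], list[str]]:
        """One condition+gene scoring pass from a gene set (fixed-point check)."""
        X = m.values
        Xr = _standardize(X, axis=1)
        Xc = _standardize(X, axis=0)
        gi = m.gene_index(genes)
        conds = self._threshold(Xr[gi].mean(axis=0), gi.size, self.t_c)
        if conds.size == 0:
            return [], []
        new_genes = self._threshold(Xc[:, conds].mean(axis=1), conds.size, self.t_g)
        return ([m.gene_ids[i] for i in new_genes],
                [m.condition_ids[j] for j in conds])


def _standardize(X: np.ndarray, axis: int) -> np.ndarray:
    mean = X.mean(axis=axis, keepdims=True)
    std = X.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(std > 0, (X - mean) / std, 0.0)
    return Z


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def isa_bicluster(m: ExpressionMatrix, p: ISAParams) -> BiclusterSet:
    """Run ISA; see :class:`IterativeSignature`."""
    est = IterativeSignature(p.t_g, p.t_c, p.n_seeds, p.rng_seed,
                             p.max_iter, p.dedup_jaccard, p.seed_size,
                             p.direction)
    return est.fit(m).biclusters_


# ---------------------------------------------------------------------------
# OPSM
# ---------------------------------------------------------------------------

class OPSM(BaseEstimator):
    """Order-Preserving SubMatrix search by partial-model growing.

    A model is an ordered tuple of columns; a row supports it when its
    values strictly increase along the model's order (ties across columns
    broken by column index).  Starting from all ordered column pairs, the
    l_models best models per size (most supporting rows, ties by
    lexicographic column order) are extended by inserting one unused column
    at any position, until no model retains at least two supporting rows.
    One bicluster is emitted per recorded model size, largest support first.
    """

    def __init__(self, l_models: int = 100, min_columns: int = 2):
        self.l_models = l_models
        self.min_columns = min_columns

    def fit(self, m: ExpressionMatrix, y=None) -> "OPSM":
        OPSMParams(self.l_models, self.min_columns)
        if m.missing_mask.any():
            raise ValueError("matrix has missing values; impute first")
        X = m.values
        n_rows, n_cols = X.shape
        if n_cols < self.min_columns:
            raise ValueError(
                f"matrix has {n_cols} columns; at least {self.min_columns} required"
            )

        def support(order: tuple[int, ...]) -> np.ndarray:
            ok = np.ones(n_rows, dtype=bool)
            for a, b in zip(order, order[1:]):
                ok &= (X[:, b] > X[:, a]) | ((X[:, b] == X[:, a]) & (b > a))
            return ok

        models = [(a, b) for a in range(n_cols) for b in range(n_cols) if a != b]
        best_per_size: list[tuple[int, tuple[int, ...], np.ndarray]] = []
        size = 2
        while models:
            scored = []
            for order in models:
                rows = support(order)
                cnt = int(rows.sum())
                if cnt >= 2:
                    scored.append((cnt, order, rows))
            if not scored:
                break
            scored.sort(key=lambda t: (-t[0], t[1]))
            scored = scored[: self.l_models]
            best_per_size.append(scored[0])
            # grow: insert one unused column at any position
            next_models: set[tuple[int, ...]] = set()
            for _, order, _ in scored:
                used = set(order)
                for c in range(n_cols):
                    if c in used:
                        continue
                    for pos in range(size + 1):
                        next_models.add(order[:pos] + (c,) + order[pos:])
            models = sorted(next_models)
            size += 1

        best_per_size.sort(key=lambda t: (-t[0], len(t[1]), t[1]))
        biclusters = []
        for cnt, order, rows in best_per_size:
            biclusters.append(
                Bicluster(
                    [m.gene_ids[i] for i in np.flatnonzero(rows)],
                    [m.condition_ids[j] for j in order],
                    source="OPSM",
                    score=float(cnt),
                )
            )
        self.biclusters_ = BiclusterSet(biclusters, m.shape)
        return self


def opsm_bicluster(m: ExpressionMatrix, p: OPSMParams) -> BiclusterSet:
    """Run OPSM; see :class:`OPSM`."""
    return OPSM(p.l_models, p.min_columns).fit(m).biclusters_


# ---------------------------------------------------------------------------
# k-means as biclusters
# ---------------------------------------------------------------------------

class KMeansBiclustering(BaseEstimator):
    """Lloyd's k-means on gene rows; each cluster becomes a bicluster
    spanning every condition (traditional clustering has no condition
    selection)."""

    def __init__(self, n_clusters: int = 100, n_iter: int = 100,
                 n_replicates: int = 10, rng_seed: int = 0):
        self.n_clusters = n_clusters
        self.n_iter = n_iter
        self.n_replicates = n_replicates
        self.rng_seed = rng_seed

    def fit(self, m: ExpressionMatrix, y=None) -> "KMeansBiclustering":
        if m.missing_mask.any():
            raise ValueError("matrix has missing values; impute first")
        if self.n_clusters > m.shape[0]:
            raise ValueError("n_clusters exceeds the number of genes")
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_replicates,
            max_iter=self.n_iter,
            random_state=self.rng_seed % (2**32),
            algorithm="lloyd",
        )
        labels = km.fit_predict(m.values)
        biclusters = []
        for lab in range(self.n_clusters):
            idx = np.flatnonzero(labels == lab)
            if idx.size == 0:
                continue
            biclusters.append(
                Bicluster(
                    [m.gene_ids[i] for i in idx],
                    list(m.condition_ids),
                    source="Kmeans",
                )
            )
        self.biclusters_ = BiclusterSet(biclusters, m.shape)
        return self


def kmeans_as_biclusters(m: ExpressionMatrix, p: KMeansParams) -> BiclusterSet:
    """Run k-means clustering as biclusters; see :class:`KMeansBiclustering`."""
    est = KMeansBiclustering(p.n_clusters, p.n_iter, p.n_replicates, p.rng_seed)
    return est.fit(m).biclusters_


# ---------------------------------------------------------------------------
# Interchange format and statistics
# ---------------------------------------------------------------------------

def write_biclusters(s: BiclusterSet, path) -> None:
    """Write the bicluster text interchange format.

    Header "#source=<name>"; then per bicluster a line of space-separated
    gene IDs, a line of condition IDs, and a blank line.
    """
    source = s.biclusters[0].source if s.biclusters else ""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#source={source}\n")
        for b in s.biclusters:
            fh.write(" ".join(b.genes) + "\n")
            fh.write(" ".join(b.conditions) + "\n")
            fh.write("\n")


def import_external_biclusters(path, m: ExpressionMatrix) -> BiclusterSet:
    """Read the bicluster interchange format, validating IDs against ``m``."""
    genes_ok = set(m.gene_ids)
    conds_ok = set(m.condition_ids)
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip() for ln in fh]
    source = ""
    body: list[str] = []
    for ln in lines:
        if ln.startswith("#source="):
            source = ln[len("#source="):]
        else:
            body.append(ln)
    # strip leading/trailing blanks, then read in gene-line/condition-line pairs
    records = [ln for ln in body]
    biclusters: list[Bicluster] = []
    i = 0
    idx = 0
    while i < len(records):
        if not records[i]:
            i += 1
            continue
        if i + 1 >= len(records) or not records[i + 1]:
            raise ValueError(f"bicluster {idx}: missing condition line")
        genes = records[i].split()
        conditions = records[i + 1].split()
        for g in genes:
            if g not in genes_ok:
                raise ValueError(f"bicluster {idx}: unknown gene ID {g!r}")
        for c in conditions:
            if c not in conds_ok:
                raise ValueError(f"bicluster {idx}: unknown condition ID {c!r}")
        biclusters.append(Bicluster(genes, conditions, source=source))
        idx += 1
        i += 2
    return BiclusterSet(biclusters, m.shape)


@dataclass
class BiclusterStats:
    count: int
    min_size: tuple[int, int] | None
    max_size: tuple[int, int] | None
    gene_coverage_pct: float
    condition_coverage_pct: float


def bicluster_stats(s: BiclusterSet) -> BiclusterStats:
    """Count, min/max bicluster dimensions (by cell count) and coverage
    percentages over the source matrix, mirroring standard biclustering
    comparison summaries."""
    if not s.biclusters:
        return BiclusterStats(0, None, None, 0.0, 0.0)
    sizes = [b.shape for b in s.biclusters]
    min_size = min(sizes, key=lambda t: (t[0] * t[1], t))
    max_size = max(sizes, key=lambda t: (t[0] * t[1], t))
    genes = set().union(*(b.gene_set for b in s.biclusters))
    conds = set().union(*(b.condition_set for b in s.biclusters))
    return BiclusterStats(
        count=len(s.biclusters),
        min_size=min_size,
        max_size=max_size,
        gene_coverage_pct=100.0 * len(genes) / s.matrix_shape[0],
        condition_coverage_pct=100.0 * len(conds) / s.matrix_shape[1],
    )
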