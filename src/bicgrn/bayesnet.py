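"""Discrete Bayesian-network structure learning with the BDe score.

Per-bicluster subnetworks are learned by steepest-ascent greedy hill
climbing over single-edge additions, deletions and reversals, scored by the
decomposable Bayesian Dirichlet equivalent (BDe) marginal likelihood with a
uniform prior of total pseudo-count ``ess`` per family.  A sparse-candidate
variant restricts each node's parents to its top mutual-information
partners.  Learned subnetworks merge by directed-edge union into one gene
network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .matrix import DiscreteMatrix, ExpressionMatrix, PreprocessConfig, discretize_quantile
from .bicluster import BiclusterSet
from .network import GeneNetwork

__all__ = [
    "DAGStructure",
    "BDeConfig",
    "SearchConfig",
    "BDeHillClimbing",
    "bde_family_score",
    "greedy_hill_climb",
    "sparse_candidate_select",
    "learn_subnetworks",
    "merge_subnetworks",
]


@dataclass
class DAGStructure:
    """A learned directed acyclic graph with per-family parent lists."""

    nodes: list[str]
    parent_sets: dict[str, list[str]]
    score: float = 0.0

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        node_set = set(self.nodes)
        for child, parents in self.parent_sets.items():
            if child not in node_set:
                raise ValueError(f"unknown child {child!r}")
            for par in parents:
                if par not in node_set:
                    raise ValueError(f"unknown parent {par!r}")
                if par == child:
                    raise ValueError(f"self-parent on {child!r}")
        for n in self.nodes:
            self.parent_sets.setdefault(n, [])
        if self._has_cycle():
            raise ValueError("parent sets contain a directed cycle")

    def _has_cycle(self) -> bool:
        state: dict[str, int] = {}

        def visit(v: str) -> bool:
            state[v] = 1
            for p in self.parent_sets.get(v, []):
                s = state.get(p, 0)
                if s == 1 or (s == 0 and visit(p)):
                    return True
            state[v] = 2
            return False

        return any(state.get(v, 0) == 0 and visit(v) for v in self.nodes)

    def edges(self) -> set[tuple[str, str]]:
        """Directed edges parent -> child."""
        return {
            (p, child)
            for child, parents in self.parent_sets.items()
            for p in parents
        }


@dataclass
class BDeConfig:
    """BDe hyperparameters: equivalent sample size and state cardinality."""

    ess: float = 1.0
    levels: int = 3

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ValueError("ess must be positive")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass
class SearchConfig:
    """Hill-climbing controls: parent cap, sparse-candidate set size, seed."""

    max_parents: int | None = None
    candidate_size: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.candidate_size is not None and self.candidate_size < 1:
            raise ValueError("candidate_size must be >= 1 when set")


# ---------------------------------------------------------------------------
# BDe family score
# ---------------------------------------------------------------------------

def _family_score_arrays(child: np.ndarray, parents: np.ndarray | None,
                         levels: int, ess: float) -> float:
    """Log BDe family term from integer state arrays.

    sum_j [lnG(a_j) - lnG(a_j + N_j)] + sum_{j,k} [lnG(a_jk + N_jk) - lnG(a_jk)]
    with a_jk = ess / (q r), a_j = ess / q, q = r^{|parents|}.
    Parent configurations never observed contribute zero.
    """
    r = levels
    n = child.shape[0]
    if parents is None or parents.size == 0:
        q = 1
        config = np.zeros(n, dtype=np.int64)
    else:
        q = r ** parents.shape[0]
        config = np.zeros(n, dtype=np.int64)
        for row in parents:
            config = config * r + row
    if n == 0:
        return 0.0
    joint = config * r + child
    _, joint_counts = np.unique(joint, return_counts=True)
    a_jk = ess / (q * r)
    a_j = ess / q
    score = float(np.sum(gammaln(a_jk + joint_counts) - gammaln(a_jk)))
    _, cfg_counts = np.unique(config, return_counts=True)
    score += float(np.sum(gammaln(a_j) - gammaln(a_j + cfg_counts)))
    return score


def bde_family_score(child: str, parents: list[str], d: DiscreteMatrix,
                     cfg: BDeConfig) -> float:
    """Log marginal likelihood of one family (child given parents)."""
    gi = {g: i for i, g in enumerate(d.gene_ids)}
    if child not in gi:
        raise KeyError(f"unknown gene {child!r}")
    for p in parents:
        if p not in gi:
            raise KeyError(f"unknown gene {p!r}")
    child_row = d.states[gi[child]]
    par = np.array([d.states[gi[p]] for p in parents]) if parents else None
    return _family_score_arrays(child_row, par, cfg.levels, cfg.ess)


# ---------------------------------------------------------------------------
# Greedy hill climbing
# ---------------------------------------------------------------------------

_EPS = 1e-9  # a move must beat the current structure by more than this


class BDeHillClimbing(BaseEstimator):
    """Steepest-ascent structure search from the empty graph.

    At each step every legal single-edge addition, deletion and reversal is
    scored; the highest strictly improving move is applied, with ties broken
    lexicographically on (move type, source, target) so runs are exactly
    reproducible.  The search respects ``max_parents`` and, when
    ``candidate_size`` is set, parents may only be added from each node's
    top-mutual-information candidate set.
    """

    def __init__(self, ess: float = 1.0, max_parents: int | None = None,
                 candidate_size: int | None = None, rng_seed: int = 0):
        self.ess = ess
        self.max_parents = max_parents
        self.candidate_size = candidate_size
        self.rng_seed = rng_seed

    def fit(self, d: DiscreteMatrix, y=None) -> "BDeHillClimbing":
        cfg = BDeConfig(ess=self.ess, levels=d.levels)
        names = d.gene_ids
        n = len(names)
        X = d.states
        levels = d.levels

        candidates: dict[int, set[int]] | None = None
        if self.candidate_size is not None and n > 1:
            cand_names = sparse_candidate_select(d, self.candidate_size)
            idx = {g: i for i, g in enumerate(names)}
            candidates = {
                idx[g]: {idx[p] for p in ps} for g, ps in cand_names.items()
            }

        parents: list[set[int]] = [set() for _ in range(n)]
        children: list[set[int]] = [set() for _ in range(n)]
        fam_cache: dict[tuple[int, tuple[int, ...]], float] = {}

        def fam(child: int, pars: frozenset[int] | set[int]) -> float:
            key = (child, tuple(sorted(pars)))
            if key not in fam_cache:
                par_arr = np.array([X[p] for p in key[1]]) if key[1] else None
                fam_cache[key] = _family_score_arrays(X[child], par_arr, levels, cfg.ess)
            return fam_cache[key]

        def reachable(src: int, dst: int, skip_edge: tuple[int, int] | None = None) -> bool:
            # DFS along child direction: True if dst reachable from src
            stack = [src]
            seen = {src}
            while stack:
                v = stack.pop()
                if v == dst:
                    return True
                for w in children[v]:
                    if skip_edge is not None and (v, w) == skip_edge:
                        continue
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            return False

        fam_scores = [fam(i, parents[i]) for i in range(n)]
        if n >= 2 and d.shape[1] >= 1:
            while True:
                best_delta = _EPS
                best_move: tuple[str, int, int] | None = None
                for move, i, j in self._moves(n, parents):
                    if move == "add":
                        if self.max_parents is not None and len(parents[j]) >= self.max_parents:
                            continue
                        if candidates is not None and i not in candidates[j]:
                            continue
                        if reachable(j, i):
                            continue
                        delta = fam(j, parents[j] | {i}) - fam_scores[j]
                    elif move == "delete":
                        delta = fam(j, parents[j] - {i}) - fam_scores[j]
                    else:  # reverse i->j to j->i
                        if self.max_parents is not None and len(parents[i]) >= self.max_parents:
                            continue
                        if candidates is not None and j not in candidates[i]:
                            continue
                        if reachable(i, j, skip_edge=(i, j)):
                            continue
                        delta = (fam(j, parents[j] - {i}) - fam_scores[j]
                                 + fam(i, parents[i] | {j}) - fam_scores[i])
                    if delta > best_delta:
                        best_delta = delta
                        best_move = (move, i, j)
                if best_move is None:
                    break
                move, i, j = best_move
                if move == "add":
                    parents[j].add(i)
                    children[i].add(j)
                    fam_scores[j] = fam(j, parents[j])
                elif move == "delete":
                    parents[j].discard(i)
                    children[i].discard(j)
                    fam_scores[j] = fam(j, parents[j])
                else:
                    parents[j].discard(i)
                    children[i].discard(j)
                    parents[i].add(j)
                    children[j].add(i)
                    fam_scores[j] = fam(j, parents[j])
                    fam_scores[i] = fam(i, parents[i])

        self.dag_ = DAGStructure(
            list(names),
            {names[j]: [names[i] for i in sorted(parents[j])] for j in range(n)},
            score=float(sum(fam_scores)),
        )
        return self

    @staticmethod
    def _moves(n: int, parents: list[set[int]]):
        """Legal move keys in lexicographic (move type, source, target) order."""
        for i in range(n):
            for j in range(n):
                if i != j and i not in parents[j]:
                    yield ("add", i, j)
        for i in range(n):
            for j in range(n):
                if i != j and i in parents[j]:
                    yield ("delete", i, j)
        for i in range(n):
            for j in range(n):
                if i != j and i in parents[j]:
                    yield ("reverse", i, j)


def greedy_hill_climb(d: DiscreteMatrix, bde: BDeConfig | None = None,
                      search: SearchConfig | None = None) -> DAGStructure:
    """Learn a DAG by greedy hill climbing; see :class:`BDeHillClimbing`."""
    bde = bde or BDeConfig()
    search = search or SearchConfig()
    if bde.levels != d.levels:
        raise ValueError(
            f"BDeConfig.levels={bde.levels} does not match matrix levels={d.levels}"
        )
    est = BDeHillClimbing(
        ess=bde.ess,
        max_parents=search.max_parents,
        candidate_size=search.candidate_size,
        rng_seed=search.rng_seed,
    )
    return est.fit(d).dag_


# ---------------------------------------------------------------------------
# Sparse candidate selection
# ---------------------------------------------------------------------------

def _mutual_information(a: np.ndarray, b: np.ndarray, levels: int) -> float:
    n = a.shape[0]
    joint = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pj > 0, pj * np.log(pj / (pa * pb)), 0.0)
    return float(terms.sum())


def sparse_candidate_select(d: DiscreteMatrix, c: int) -> dict[str, list[str]]:
    """Top-``c`` mutual-information candidate parents per node.

    Ties resolve by gene order in the matrix so selection is deterministic.
    With ``c >= n - 1`` every other node is a candidate (warning emitted).
    """
    if c < 1:
        raise ValueError("candidate set size must be >= 1")
    names = d.gene_ids
    n = len(names)
    if c >= n - 1:
        warnings.warn("candidate size >= node count - 1; all others are candidates",
                      stacklevel=2)
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = _mutual_information(d.states[i], d.states[j], d.levels)
    out: dict[str, list[str]] = {}
    for j in range(n):
        others = [i for i in range(n) if i != j]
        others.sort(key=lambda i: (-mi[i, j], i))
        out[names[j]] = [names[i] for i in others[:c]]
    return out


# ---------------------------------------------------------------------------
# Per-bicluster learning and merging
# ---------------------------------------------------------------------------

def learn_subnetworks(m: ExpressionMatrix, s: BiclusterSet,
                      pre: PreprocessConfig | None = None,
                      bde: BDeConfig | None = None,
                      search: SearchConfig | None = None) -> list[DAGStructure]:
    """Learn one DAG per bicluster, on the submatrix restricted to the
    bicluster's genes and conditions (discretized per gene).

    Biclusters with fewer than 2 conditions or fewer than 2 genes yield an
    empty DAG over their genes.
    """
    pre = pre or PreprocessConfig()
    bde = bde or BDeConfig(levels=pre.discretization_levels)
    search = search or SearchConfig()
    if bde.levels != pre.discretization_levels:
        raise ValueError("BDeConfig.levels must match PreprocessConfig.discretization_levels")
    dags: list[DAGStructure] = []
    for b in s:
        gi = m.gene_index(b.genes)
        ci = m.condition_index(b.conditions)
        if len(b.genes) < 2 or len(b.conditions) < 2:
            dags.append(DAGStructure(list(b.genes), {g: [] for g in b.genes}))
            continue
        if len(b.conditions) < 3 * bde.levels:
            warnings.warn(
                f"bicluster with {len(b.conditions)} conditions: small sample "
                f"for {bde.levels}-level families",
                stacklevel=2,
            )
        sub = ExpressionMatrix(
            list(b.genes), list(b.conditions),
            m.values[np.ix_(gi, ci)], m.missing_mask[np.ix_(gi, ci)],
        )
        d = discretize_quantile(sub, levels=bde.levels)
        dags.append(greedy_hill_climb(d, bde, search))
    return dags


def merge_subnetworks(dags: list[DAGStructure]) -> GeneNetwork:
    """Union of directed edges over all subnetworks, duplicates removed."""
    edges: set[tuple[str, str]] = set()
    universe: set[str] = set()
    for dag in dags:
        universe.update(dag.nodes)
        edges.update(dag.edges())
    return GeneNetwork(edges, universe)
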