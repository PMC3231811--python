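"""Seeded synthetic fixtures: planted biclusters, Bayesian networks and
gold-standard networks with module-structured annotations.

The expression generator overlays coherent blocks — constant shifts,
additive row+column effects, or order-preserving rows — on a Gaussian
background with optional uniform missingness, returning the planted
biclusters as ground truth.  The Bayesian-network generator samples a
random DAG with Dirichlet-drawn conditional tables and draws ancestral
samples.  Together they let every pipeline stage be exercised and scored
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import DiscreteMatrix, ExpressionMatrix
from .bicluster import Bicluster
from .bayesnet import DAGStructure, merge_subnetworks
from .enrichment import AnnotationMap
from .network import GeneNetwork

__all__ = [
    "PlantSpec",
    "PlantedBN",
    "simulate_expression",
    "simulate_bn_data",
    "simulate_gold_and_annotations",
]


@dataclass
class PlantSpec:
    """Layout of an expression matrix with implanted biclusters.

    blocks: (n_genes, n_conditions, pattern, amplitude) per bicluster with
    pattern one of {"constant", "additive", "order_preserving"}.  Blocks are
    placed on disjoint consecutive gene/condition ranges.
    """

    n_genes: int = 100
    n_conditions: int = 40
    noise_sd: float = 1.0
    missing_fraction: float = 0.0
    blocks: list[tuple[int, int, str, float]] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_conditions < 1:
            raise ValueError("matrix dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")
        if sum(b[0] for b in self.blocks) > self.n_genes or \
           sum(b[1] for b in self.blocks) > self.n_conditions:
            raise ValueError("blocks exceed matrix bounds")
        for b in self.blocks:
            if b[2] not in {"constant", "additive", "order_preserving"}:
                raise ValueError(f"unknown pattern {b[2]!r}")
            if not np.isfinite(b[3]):
                raise ValueError("amplitude must be finite")


def simulate_expression(spec: PlantSpec) -> tuple[ExpressionMatrix, list[Bicluster]]:
    """Gaussian background with implanted coherent blocks.

    Returns the matrix and the list of ground-truth planted biclusters
    (in block order).
    """
    rng = np.random.default_rng(spec.rng_seed)
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_conditions))
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    cond_ids = [f"C{j:03d}" for j in range(spec.n_conditions)]
    truth: list[Bicluster] = []
    g0 = c0 = 0
    for gn, cn, pattern, amp in spec.blocks:
        gi = slice(g0, g0 + gn)
        ci = slice(c0, c0 + cn)
        if pattern == "constant":
            values[gi, ci] += amp
        elif pattern == "additive":
            row_eff = rng.uniform(-amp, amp, size=gn)
            col_eff = rng.uniform(-amp, amp, size=cn)
            values[gi, ci] += row_eff[:, None] + col_eff[None, :]
        else:  # order_preserving: increasing staircase along a hidden column order
            order = rng.permutation(cn)
            steps = amp * (np.argsort(order) + 1).astype(float)
            values[gi, ci] += steps[None, :]
        truth.append(
            Bicluster(gene_ids[gi], cond_ids[ci], source=f"planted:{pattern}")
        )
        g0 += gn
        c0 += cn
    mask = rng.random(values.shape) < spec.missing_fraction
    values = np.where(mask, np.nan, values)
    return ExpressionMatrix(gene_ids, cond_ids, values, mask), truth


@dataclass
class PlantedBN:
    """A random discrete Bayesian network to sample training data from."""

    n_nodes: int = 3
    edge_probability: float = 0.5
    levels: int = 3
    n_samples: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_samples < 1:
            raise ValueError("n_nodes and n_samples must be positive")
        if not 0 <= self.edge_probability <= 1:
            raise ValueError("edge_probability must be in [0, 1]")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


def simulate_bn_data(p: PlantedBN) -> tuple[DAGStructure, DiscreteMatrix]:
    """Sample a random DAG, Dirichlet(1) conditional tables, and data.

    Edges point forward along a random node order, each kept with
    ``edge_probability``; samples are drawn ancestrally.  The sample matrix
    has nodes as rows (genes) and samples as columns (conditions).
    """
    rng = np.random.default_rng(p.rng_seed)
    names = [f"G{i:04d}" for i in range(p.n_nodes)]
    order = rng.permutation(p.n_nodes)
    parents: dict[str, list[str]] = {n: [] for n in names}
    parent_idx: dict[int, list[int]] = {i: [] for i in range(p.n_nodes)}
    for a_pos in range(p.n_nodes):
        for b_pos in range(a_pos + 1, p.n_nodes):
            if rng.random() < p.edge_probability:
                a, b = int(order[a_pos]), int(order[b_pos])
                parents[names[b]].append(names[a])
                parent_idx[b].append(a)
    for b in parents:
        parents[b].sort()

    r = p.levels
    cpts: dict[int, np.ndarray] = {}
    for i in range(p.n_nodes):
        q = r ** len(parent_idx[i])
        cpts[i] = rng.dirichlet(np.ones(r), size=q)

    states = np.zeros((p.n_nodes, p.n_samples), dtype=int)
    topo = [int(v) for v in order]
    for s in range(p.n_samples):
        for i in topo:
            cfg = 0
            for par in parent_idx[i]:
                cfg = cfg * r + states[par, s]
            states[i, s] = rng.choice(r, p=cpts[i][cfg])

    dag = DAGStructure(names, parents)
    cond_ids = [f"S{j:05d}" for j in range(p.n_samples)]
    return dag, DiscreteMatrix(names, cond_ids, states, p.levels)


def simulate_gold_and_annotations(
    truth_dags: list[DAGStructure],
    extra_edges: int = 0,
    terms_per_module: int = 1,
    rng_seed: int = 0,
    population: set[str] | None = None,
    background_annotation_rate: float = 0.05,
    n_background_terms: int = 10,
) -> tuple[GeneNetwork, AnnotationMap]:
    """Gold network = union of truth edges plus random distractors;
    annotations give each planted module its own synthetic term(s) covering
    all module genes, plus uniform background annotations.
    """
    rng = np.random.default_rng(rng_seed)
    merged = merge_subnetworks(truth_dags)
    universe = sorted(set(population or set()) | merged.gene_universe)
    edges = set(merged.edges)
    n = len(universe)
    attempts = 0
    added = 0
    while added < extra_edges and attempts < 100 * max(extra_edges, 1):
        a, b = rng.integers(0, n, size=2)
        attempts += 1
        if a == b:
            continue
        e = (universe[a], universe[b])
        if e in edges:
            continue
        edges.add(e)
        added += 1
    gold = GeneNetwork(edges, set(universe))

    pairs: list[tuple[str, str]] = []
    for mi, dag in enumerate(truth_dags):
        for ti in range(terms_per_module):
            term = f"MODULE:{mi:03d}.{ti}"
            pairs.extend((g, term) for g in dag.nodes)
    for bi in range(n_background_terms):
        term = f"BG:{bi:03d}"
        for g in universe:
            if rng.random() < background_annotation_rate:
                pairs.append((g, term))
    annotations = AnnotationMap.from_pairs(pairs, set(universe))
    return gold, annotations
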