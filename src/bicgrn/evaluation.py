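"""Gold-standard evaluation of predicted gene networks.

Confusion matrices are counted over the full ordered-pair universe
N(N-1) of the declared gene set (directed counting; undirected gold
interactions are expanded to both orientations upstream).  Single-point
ROC/PR areas summarise a network prediction the way gene-network
challenge evaluations do, and an indirect-edge reclassification converts
false positives whose endpoints are joined by a two-hop gold path into
true positives (with the symmetric TN -> FN change).  Topology statistics
(diameter, density, average neighbour count) are computed on the
undirected view.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx

from .network import GeneNetwork

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "TopologyStats",
    "confusion_matrix",
    "auc_from_confusion",
    "modified_reclassify",
    "topology_stats",
    "round_half_up",
    "write_evaluation_tsv",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    recall = tpr


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    auroc: float
    aupr: float
    modified: ConfusionMatrix | None = None
    modified_auroc: float | None = None
    modified_aupr: float | None = None
    fp_to_tp: int = 0
    tn_to_fn: int = 0


@dataclass
class TopologyStats:
    diameter: int
    density: float
    avg_neighbors: float


def _check_edges(net: GeneNetwork, universe: set, name: str) -> None:
    for a, b in net.edges:
        if a not in universe or b not in universe:
            raise ValueError(f"{name} edge ({a!r}, {b!r}) has endpoint outside universe")


def confusion_matrix(predicted: GeneNetwork, gold: GeneNetwork,
                     universe: set | None = None) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over all ordered gene pairs of the universe.

    The universe defaults to the union of both networks' gene sets; its
    size N implies TP+FP+TN+FN = N(N-1).
    """
    if universe is None:
        universe = set(predicted.gene_universe) | set(gold.gene_universe)
    universe = set(universe)
    _check_edges(predicted, universe, "predicted")
    _check_edges(gold, universe, "gold")
    n = len(universe)
    total = n * (n - 1)
    tp = len(predicted.edges & gold.edges)
    fp = len(predicted.edges - gold.edges)
    fn = len(gold.edges - predicted.edges)
    tn = total - tp - fp - fn
    return ConfusionMatrix(tp, fp, tn, fn)


def auc_from_confusion(c: ConfusionMatrix) -> tuple[float, float]:
    """Single-operating-point ROC and PR areas by trapezoidal interpolation.

    The ROC curve runs (0,0) -> (FPR,TPR) -> (1,1), so
    AUROC = (TPR + 1 - FPR) / 2.  The PR curve is anchored at (0,1),
    passes (recall, precision) and ends at (1, prevalence).
    """
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("need at least one positive and one negative pair")
    auroc = (c.tpr + 1.0 - c.fpr) / 2.0
    prevalence = (c.tp + c.fn) / c.total
    r, p = c.recall, c.precision
    aupr = r * (1.0 + p) / 2.0 + (1.0 - r) * (p + prevalence) / 2.0
    return auroc, aupr


def _two_hop_pairs(gold: GeneNetwork) -> set[tuple[str, str]]:
    """Ordered pairs joined by a path of exactly two undirected gold edges."""
    adj: dict[str, set[str]] = {}
    for a, b in gold.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    pairs: set[tuple[str, str]] = set()
    for mid, nbrs in adj.items():
        for a in nbrs:
            for b in nbrs:
                if a != b:
                    pairs.add((a, b))
    return pairs


def modified_reclassify(predicted: GeneNetwork, gold: GeneNetwork,
                        universe: set | None = None) -> EvaluationReport:
    """Indirect-edge reclassification against an undirected gold view.

    An FP ordered pair (a, b) becomes TP iff some intermediate gene c has
    gold interactions {a,c} and {c,b}; a TN pair becomes FN under the same
    two-hop condition.  Longer indirect paths do not reclassify.  The
    report carries both the original and modified confusion matrices and
    the two transfer counts; the pair-universe total is conserved.
    """
    if universe is None:
        universe = set(predicted.gene_universe) | set(gold.gene_universe)
    universe = set(universe)
    orig = confusion_matrix(predicted, gold, universe)
    auroc, aupr = auc_from_confusion(orig)
    twohop = {
        (a, b) for a, b in _two_hop_pairs(gold)
        if a in universe and b in universe
    }
    fp_pairs = predicted.edges - gold.edges
    fp_to_tp = len(fp_pairs & twohop)
    # TN pairs with a two-hop connection: two-hop, not a gold edge, not predicted
    tn_to_fn = len(twohop - gold.edges - predicted.edges)
    mod = ConfusionMatrix(
        orig.tp + fp_to_tp,
        orig.fp - fp_to_tp,
        orig.tn - tn_to_fn,
        orig.fn + tn_to_fn,
    )
    if mod.tp + mod.fn > 0 and mod.fp + mod.tn > 0:
        mod_auroc, mod_aupr = auc_from_confusion(mod)
    else:  # reclassification can exhaust one class on tiny universes
        mod_auroc = mod_aupr = None
    return EvaluationReport(
        confusion=orig,
        auroc=auroc,
        aupr=aupr,
        modified=mod,
        modified_auroc=mod_auroc,
        modified_aupr=mod_aupr,
        fp_to_tp=fp_to_tp,
        tn_to_fn=tn_to_fn,
    )


def topology_stats(net: GeneNetwork) -> TopologyStats:
    """Undirected diameter (largest component), density and mean degree.

    avg_neighbors = 2E/N over the declared gene universe;
    density = avg_neighbors / (N - 1); diameter = max eccentricity within
    the largest connected component.
    """
    if not net.edges:
        raise ValueError("empty network")
    g = nx.Graph()
    g.add_nodes_from(net.gene_universe)
    g.add_edges_from(net.edges)
    n = len(net.gene_universe)
    e = g.number_of_edges()
    avg_neighbors = 2.0 * e / n
    density = avg_neighbors / (n - 1) if n > 1 else 0.0
    largest = max(nx.connected_components(g), key=len)
    diameter = nx.diameter(g.subgraph(largest))
    return TopologyStats(diameter=int(diameter), density=density,
                         avg_neighbors=avg_neighbors)


def round_half_up(x: float, places: int = 4) -> float:
    """Round half away from zero at the given decimal place (report formatting)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def write_evaluation_tsv(reports: dict[str, EvaluationReport], path,
                         modified: bool = False) -> None:
    """Write evaluation rows (one per method) as TSV."""
    cols = ["Methods", "EdgeCount", "TP", "FP", "TN", "FN"]
    if modified:
        cols += ["FP to TP", "TN to FN"]
    cols += ["AUROC", "AUPR"]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for name in sorted(reports):
            r = reports[name]
            c = r.modified if modified and r.modified is not None else r.confusion
            auroc = r.modified_auroc if modified and r.modified_auroc is not None else r.auroc
            aupr = r.modified_aupr if modified and r.modified_aupr is not None else r.aupr
            row = [name, str(r.confusion.tp + r.confusion.fp),
                   str(c.tp), str(c.fp), str(c.tn), str(c.fn)]
            if modified:
                row += [str(r.fp_to_tp), str(r.tn_to_fn)]
            row += [f"{round_half_up(auroc):.4f}", f"{round_half_up(aupr):.4f}"]
            fh.write("\t".join(row) + "\n")
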