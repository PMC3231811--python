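"""Directed gene-network container and SIF / edge-list IO."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = ["GeneNetwork", "read_network", "write_network"]


@dataclass
class GeneNetwork:
    """A set of directed gene-gene edges over a declared gene universe.

    Self-edges are forbidden; the universe must contain every edge endpoint.
    """

    edges: set[tuple[str, str]]
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = set(map(tuple, self.edges))
        endpoints = {g for e in self.edges for g in e}
        self.gene_universe = set(self.gene_universe) | endpoints
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def undirected_edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}


def read_network(path, directed: bool = True) -> GeneNetwork:
    """Read a network from SIF ("src relation tgt") or 2-column TSV.

    With ``directed=False`` each record expands to both orientations (the
    convention for interaction-database gold standards, which are
    undirected).  Self-edges are skipped with a warning.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, _, b = parts
            else:
                raise ValueError(f"{path}: line {lineno}: malformed record {line!r}")
            if a == b:
                warnings.warn(f"line {lineno}: self-edge on {a!r} skipped", stacklevel=2)
                continue
            nodes.update((a, b))
            edges.add((a, b))
            if not directed:
                edges.add((b, a))
    return GeneNetwork(edges, nodes)


def write_network(net: GeneNetwork, path, fmt: str = "tsv") -> None:
    """Write a network as 2-column TSV or SIF ("src pd tgt"), sorted edges."""
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in net.sorted_edges():
            if fmt == "sif":
                fh.write(f"{a} pd {b}\n")
            else:
                fh.write(f"{a}\t{b}\n")
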