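"""Cellular interaction graphs.

A multicellular group is modeled as an undirected, unweighted graph on
``n_cells`` cells: an edge means the two cells may share viability
returns.  The graph families provided here cover the morphologies of
simple multicellular organisms (filaments, trees, rings) together with
reference topologies (complete, disconnected, complete bipartite) and
Erdős–Rényi random graphs for sparsity sweeps.

Cell indices are 0-based everywhere, including the file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "TOPOLOGY_KINDS",
    "make_topology",
    "degrees_with_self",
    "read_graph",
    "write_graph",
]

TOPOLOGY_KINDS = (
    "ring",
    "complete",
    "disconnected",
    "balanced_bipartite",
    "filament",
    "kary_tree",
    "erdos_renyi",
)


def _canonical_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Topology:
    """Undirected, unweighted interaction graph on ``n_cells`` cells.

    Edges are stored as a frozenset of sorted index pairs; no
    self-edges are allowed (self-sharing enters through the sharing
    matrix, not the topology).
    """

    n_cells: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be a positive integer")
        canon = set()
        for e in self.edges:
            i, j = e
            if i == j:
                raise ValueError(f"self-edge ({i}, {j}) is not allowed")
            if not (0 <= i < self.n_cells and 0 <= j < self.n_cells):
                raise ValueError(
                    f"edge ({i}, {j}) has an endpoint outside [0, {self.n_cells})"
                )
            canon.add(_canonical_edge(i, j))
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric boolean adjacency matrix with an all-false diagonal."""
        a = np.zeros((self.n_cells, self.n_cells), dtype=bool)
        for i, j in self.edges:
            a[i, j] = a[j, i] = True
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def degrees_with_self(self) -> np.ndarray:
        """Neighbor counts n_i = degree + 1 (a cell counts itself)."""
        return self.degrees() + 1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Topology":
        nodes = sorted(g.nodes())
        relabel = {u: k for k, u in enumerate(nodes)}
        edges = frozenset(
            _canonical_edge(relabel[u], relabel[v]) for u, v in g.edges()
        )
        return cls(n_cells=g.number_of_nodes(), edges=edges)


def make_topology(
    kind: str,
    n: int,
    *,
    p: float | None = None,
    branching: int | None = None,
    seed: int | None = None,
) -> Topology:
    """Construct a named interaction graph on ``n`` cells.

    Parameters
    ----------
    kind
        One of ``ring`` (each cell linked to its two nearest neighbors
        on a cycle), ``complete``, ``disconnected`` (no edges),
        ``balanced_bipartite`` (complete bipartite on two equal
        halves), ``filament`` (open path), ``kary_tree`` (rooted tree
        filled level by level, each node up to ``branching`` children)
        or ``erdos_renyi`` (each possible edge present independently
        with probability ``p``).
    n
        Number of cells (``>= 1``; ``>= 3`` for a ring, even for the
        balanced bipartite graph).
    p, branching, seed
        Family-specific parameters; ``seed`` makes ``erdos_renyi``
        reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "ring":
        if n < 3:
            raise ValueError("a ring requires n >= 3")
        g = nx.cycle_graph(n)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "disconnected":
        g = nx.empty_graph(n)
    elif kind == "balanced_bipartite":
        if n % 2 != 0:
            raise ValueError("balanced_bipartite requires an even n")
        g = nx.complete_bipartite_graph(n // 2, n // 2)
    elif kind == "filament":
        g = nx.path_graph(n)
    elif kind == "kary_tree":
        if branching is None or branching < 1:
            raise ValueError("kary_tree requires branching >= 1")
        g = nx.full_rary_tree(branching, n)
    elif kind == "erdos_renyi":
        if p is None or not (0.0 <= p <= 1.0):
            raise ValueError("erdos_renyi requires p in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown topology kind {kind!r}")
    return Topology.from_networkx(g)


def degrees_with_self(t: Topology) -> np.ndarray:
    """Per-cell neighbor counts n_i, counting the cell itself."""
    return t.degrees_with_self()


def write_graph(t: Topology, path: str | Path, format: str = "edge_list") -> None:
    """Write a topology as a plain-text edge list or as GraphML."""
    path = Path(path)
    if format == "edge_list":
        lines = [f"# n_cells: {t.n_cells}"]
        lines += [f"{i} {j}" for i, j in sorted(t.edges)]
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(t.to_networkx(), path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path: str | Path, format: str = "edge_list") -> Topology:
    """Read a topology written by :func:`write_graph`.

    Edge lists are whitespace-separated 0-based integer pairs, one per
    line; ``#`` starts a comment.  A ``# n_cells: N`` comment fixes the
    cell count (needed for trailing isolated cells); otherwise the
    count is inferred as the largest index plus one.  Self-edges,
    duplicate edges and malformed lines are rejected.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return Topology.from_networkx(nx.convert_node_labels_to_integers(g))
    if format != "edge_list":
        raise ValueError(f"unknown graph format {format!r}")
    n_cells = None
    edges: set[tuple[int, int]] = set()
    max_idx = -1
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("n_cells"):
                n_cells = int(body.split(":", 1)[1])
            continue
        if "#" in line:
            line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two integers, got {raw!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer entry in {raw!r}") from exc
        if i < 0 or j < 0:
            raise ValueError(f"{path}:{lineno}: negative cell index in {raw!r}")
        if i == j:
            raise ValueError(f"{path}:{lineno}: self-edge {i}-{j} is not allowed")
        e = _canonical_edge(i, j)
        if e in edges:
            raise ValueError(f"{path}:{lineno}: duplicate edge {i}-{j}")
        edges.add(e)
        max_idx = max(max_idx, i, j)
    if n_cells is None:
        n_cells = max_idx + 1
    if n_cells < 1:
        raise ValueError(f"{path}: empty edge list with no '# n_cells' header")
    return Topology(n_cells=n_cells, edges=frozenset(edges))
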