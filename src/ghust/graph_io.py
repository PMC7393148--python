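"""Reading, validation and canonicalization of input graphs.

All downstream computation operates on :class:`Graph`, an immutable simple
undirected graph with string node labels.  Inputs in any supported format are
*simplified* on read: self-loops are dropped, parallel edges collapsed, and
any direction or weight information discarded (with a warning), because the
topology fingerprint is defined only for simple undirected unweighted graphs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "GraphInputError",
    "read_graph",
    "write_edgelist",
    "canonicalize",
]


class GraphInputError(ValueError):
    """Raised for unusable graph input (empty, malformed, disconnected)."""


@dataclass(frozen=True)
class Graph:
    """Simple undirected unweighted graph.

    Node labels are opaque strings.  Internal integer indices follow first
    appearance order of the labels at construction time, which makes every
    derived table and metric deterministic for a given input.

    Attributes
    ----------
    labels:
        Node labels in canonical (first-appearance) order.
    adjacency:
        ``adjacency[i]`` is the frozen set of neighbor *indices* of node ``i``.
    """

    labels: tuple[str, ...]
    adjacency: tuple[frozenset[int], ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            object.__setattr__(
                self, "_index", {lab: i for i, lab in enumerate(self.labels)}
            )
        if len(self._index) != len(self.labels):
            raise GraphInputError("duplicate node labels")
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise GraphInputError(f"self-loop at node {self.labels[i]!r}")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise GraphInputError("asymmetric adjacency")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
    ) -> "Graph":
        """Build a graph from label pairs, dropping loops and duplicates.

        ``nodes`` may pre-seed the label order (e.g. to keep isolated nodes
        or force an ordering); otherwise labels are ordered by first
        appearance in the edge stream.
        """
        index: dict[str, int] = {}
        if nodes is not None:
            for lab in nodes:
                index.setdefault(str(lab), len(index))
        adj: list[set[int]] = [set() for _ in index]

        def _idx(lab: str) -> int:
            i = index.get(lab)
            if i is None:
                i = index[lab] = len(index)
                adj.append(set())
            return i

        n_loops = n_dups = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                _idx(u)
                continue
            iu, iv = _idx(u), _idx(v)
            if iv in adj[iu]:
                n_dups += 1
                continue
            adj[iu].add(iv)
            adj[iv].add(iu)
        if n_loops or n_dups:
            logger.warning(
                "simplified input: dropped %d self-loop(s) and %d duplicate edge(s)",
                n_loops,
                n_dups,
            )
        labels = tuple(index)
        return cls(labels, tuple(frozenset(s) for s in adj))

    @classmethod
    def from_networkx(cls, g: "nx.Graph") -> "Graph":
        if g.is_directed() or g.is_multigraph():
            logger.warning("degrading %s to a simple undirected graph", type(g).__name__)
            g = nx.Graph(g.to_undirected())
        return cls.from_edges(
            ((str(u), str(v)) for u, v in g.edges()),
            nodes=[str(n) for n in g.nodes()],
        )

    def to_networkx(self) -> "nx.Graph":
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges())
        return g

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency) // 2

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self.adjacency], dtype=np.int64)

    def edges(self) -> Iterator[tuple[str, str]]:
        """Edges as label pairs, each once, in canonical index order."""
        for i, nbrs in enumerate(self.adjacency):
            for j in sorted(nbrs):
                if i < j:
                    yield self.labels[i], self.labels[j]

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __repr__(self) -> str:  # compact: the default dataclass repr is huge
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# -- readers ---------------------------------------------------------------


def _read_edgelist(path: Path) -> Graph:
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) < 2:
                raise GraphInputError(f"{path}:{lineno}: expected two node labels")
            if len(parts) > 2:
                logger.warning(
                    "%s:%d: ignoring %d extra column(s) (weights/attributes)",
                    path,
                    lineno,
                    len(parts) - 2,
                )
            edges.append((parts[0], parts[1]))
    if not edges:
        raise GraphInputError(f"{path}: no edges found")
    return Graph.from_edges(edges)


def _read_adjacency(path: Path) -> Graph:
    with open(path) as fh:
        sample = fh.read(4096)
    delimiter = "," if "," in sample else None
    try:
        mat = np.loadtxt(path, delimiter=delimiter, dtype=float)
    except ValueError as exc:
        raise GraphInputError(f"{path}: cannot parse adjacency matrix: {exc}") from exc
    mat = np.atleast_2d(mat)
    if mat.shape[0] != mat.shape[1]:
        raise GraphInputError(f"{path}: adjacency matrix is not square: {mat.shape}")
    if not np.array_equal(mat, mat.T):
        raise GraphInputError(f"{path}: adjacency matrix is not symmetric")
    if mat.shape[0] == 0:
        raise GraphInputError(f"{path}: empty adjacency matrix")
    nonbinary = np.setdiff1d(np.unique(mat), [0.0, 1.0])
    if nonbinary.size:
        logger.warning("%s: non-binary entries treated as edges (weights dropped)", path)
    n = mat.shape[0]
    labels = [str(i) for i in range(n)]
    ii, jj = np.nonzero(mat)
    return Graph.from_edges(
        ((labels[i], labels[j]) for i, j in zip(ii, jj) if i < j), nodes=labels
    )


_FORMATS = ("edgelist", "graphml", "gml", "adjacency")


def read_graph(path: str | Path, format: str = "edgelist") -> Graph:
    """Read a graph file and return the simplified :class:`Graph`.

    Parameters
    ----------
    path:
        Input file.  Edge lists are whitespace- or comma-separated label
        pairs, one per line, ``#`` comments allowed; adjacency input is a
        square symmetric 0/1 matrix (CSV or whitespace).
    format:
        One of ``edgelist``, ``graphml``, ``gml``, ``adjacency``.
    """
    path = Path(path)
    if not path.is_file():
        raise GraphInputError(f"no such file: {path}")
    if format == "edgelist":
        g = _read_edgelist(path)
    elif format == "graphml":
        g = Graph.from_networkx(nx.read_graphml(path))
    elif format == "gml":
        g = Graph.from_networkx(nx.read_gml(path, label="label"))
    elif format == "adjacency":
        g = _read_adjacency(path)
    else:
        raise GraphInputError(f"unknown format {format!r}; choose from {_FORMATS}")
    if g.n_nodes == 0:
        raise GraphInputError(f"{path}: empty graph")
    return g


def write_edgelist(g: Graph, path: str | Path, delimiter: str = " ") -> None:
    """Write the graph as a plain edge list (round-trips with ``read_graph``)."""
    with open(path, "w", newline="") as fh:
        if delimiter == ",":
            writer = csv.writer(fh)
            writer.writerows(g.edges())
        else:
            for u, v in g.edges():
                fh.write(f"{u}{delimiter}{v}\n")


# -- canonicalization ------------------------------------------------------


def _components(g: Graph) -> list[list[int]]:
    seen = [False] * g.n_nodes
    comps: list[list[int]] = []
    for start in range(g.n_nodes):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in g.adjacency[i]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def canonicalize(g: Graph, connectivity_policy: str = "require") -> Graph:
    """Return a connected graph per the chosen policy.

    ``require`` raises on disconnected input; ``largest_component`` keeps the
    induced subgraph on the largest component (ties broken by the
    lexicographically smallest sorted label tuple, so the result is
    deterministic) and logs what was dropped.  The operation is idempotent
    and preserves the relative canonical order of the surviving nodes.
    """
    comps = _components(g)
    if len(comps) <= 1:
        return g
    if connectivity_policy == "require":
        raise GraphInputError(
            f"graph is disconnected ({len(comps)} components); "
            "use connectivity_policy='largest_component' to keep the largest"
        )
    if connectivity_policy != "largest_component":
        raise ValueError(f"unknown connectivity policy {connectivity_policy!r}")
    size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == size]
    best = min(tied, key=lambda c: sorted(g.labels[i] for i in c))
    keep = set(best)
    sub_edges = [
        (g.labels[i], g.labels[j])
        for i, j_set in enumerate(g.adjacency)
        if i in keep
        for j in j_set
        if i < j and j in keep
    ]
    out = Graph.from_edges(sub_edges, nodes=[g.labels[i] for i in best])
    logger.warning(
        "kept largest component: dropped %d node(s) and %d edge(s)",
        g.n_nodes - out.n_nodes,
        g.n_edges - out.n_edges,
    )
    return out
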