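"""Per-node orbit counting for 2- and 3-node graphlets.

The three graphlets of order at most three are the edge (G0), the 3-node
path (G1) and the triangle (G2).  Their automorphism orbits are the edge
endpoint (O0), the path end (O1), the path center (O2) and the triangle
vertex (O3).  For every node ``i`` the *touch count* ``O_t,i`` is the number
of induced graphlets in which ``i`` occupies orbit ``t``; O0 equals the node
degree.

Two counters are provided: :func:`count_orbits` uses the closed forms

    O0_i = d_i
    O3_i = t_i                      (triangles through i)
    O2_i = C(d_i, 2) - t_i          (non-adjacent neighbor pairs)
    O1_i = sum_{j in N(i)} (d_j - 1) - 2 t_i

which cost O(sum_i d_i^2) overall, and :func:`brute_force_orbits` enumerates
every 3-subset of nodes in O(N^3) as an independent oracle.  The two must
agree exactly; the test suite enforces this on a battery of random graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .graph_io import Graph

__all__ = [
    "OrbitTable",
    "IndicatorTable",
    "count_orbits",
    "brute_force_orbits",
    "indicators",
    "graphlet_totals",
]


@dataclass(frozen=True)
class OrbitTable:
    """Per-node touch counts of orbits O0-O3, in canonical node order."""

    labels: tuple[str, ...]
    o0: np.ndarray
    o1: np.ndarray
    o2: np.ndarray
    o3: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("o0", "o1", "o2", "o3"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            if (arr < 0).any():
                raise ValueError(f"negative counts in {name}")

    @property
    def triangles_per_node(self) -> np.ndarray:
        """t_i, the number of triangles containing node i (alias of O3)."""
        return self.o3

    def validate(self) -> None:
        """Assert the structural identities every orbit table must satisfy."""
        if self.o0.sum() % 2:
            raise AssertionError("sum of degrees is odd")
        if self.o1.sum() != 2 * self.o2.sum():
            raise AssertionError("sum O1 != 2 * sum O2 (each path has 2 ends, 1 center)")
        if self.o3.sum() % 3:
            raise AssertionError("sum O3 not divisible by 3")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrbitTable):
            return NotImplemented
        return self.labels == other.labels and all(
            np.array_equal(getattr(self, a), getattr(other, a))
            for a in ("o0", "o1", "o2", "o3")
        )


@dataclass(frozen=True)
class IndicatorTable:
    """Binary per-node flags derived from an :class:`OrbitTable`.

    ``p0..p3`` flag whether a node touches the orbit at all; ``u2`` flags
    nodes that touch O2 exactly once (candidate string middles) and ``u3``
    flags nodes in no triangle.
    """

    labels: tuple[str, ...]
    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    u2: np.ndarray
    u3: np.ndarray


def count_orbits(g: Graph) -> OrbitTable:
    """Count O0-O3 per node via the degree/triangle closed forms.

    Per-node triangle counts come from neighbor-set intersection, iterating
    each edge from its lower-degree endpoint, so the whole computation is
    O(|V| d^2) with d the maximum degree.
    """
    n = g.n_nodes
    adj = g.adjacency
    deg = g.degrees()
    tri = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in adj[i]:
            if i < j:
                small, large = (adj[i], adj[j]) if deg[i] <= deg[j] else (adj[j], adj[i])
                for w in small:
                    if w > j and w in large:
                        tri[i] += 1
                        tri[j] += 1
                        tri[w] += 1
    nbr_deg_sum = np.array([sum(deg[j] for j in adj[i]) for i in range(n)], dtype=np.int64)
    o0 = deg
    o3 = tri
    o2 = deg * (deg - 1) // 2 - tri
    o1 = nbr_deg_sum - deg - 2 * tri
    table = OrbitTable(g.labels, o0, o1, o2, o3)
    table.validate()
    return table


def brute_force_orbits(g: Graph, max_nodes: int = 200) -> OrbitTable:
    """Count orbits by enumerating all 3-subsets of nodes (O(N^3) oracle).

    Classifies each induced 3-node subgraph as disconnected, path (G1) or
    triangle (G2) and increments the member nodes' orbit counts directly
    from the definitions, with no shared code with :func:`count_orbits`.
    """
    n = g.n_nodes
    if n > max_nodes:
        raise ValueError(f"brute force capped at {max_nodes} nodes (got {n})")
    adj = g.adjacency
    o1 = np.zeros(n, dtype=np.int64)
    o2 = np.zeros(n, dtype=np.int64)
    o3 = np.zeros(n, dtype=np.int64)
    for a, b, c in itertools.combinations(range(n), 3):
        ab = b in adj[a]
        ac = c in adj[a]
        bc = c in adj[b]
        m = ab + ac + bc
        if m == 3:
            o3[a] += 1
            o3[b] += 1
            o3[c] += 1
        elif m == 2:
            if ab and ac:
                center, ends = a, (b, c)
            elif ab and bc:
                center, ends = b, (a, c)
            else:
                center, ends = c, (a, b)
            o2[center] += 1
            o1[ends[0]] += 1
            o1[ends[1]] += 1
    return OrbitTable(g.labels, g.degrees(), o1, o2, o3)


def indicators(ot: OrbitTable) -> IndicatorTable:
    """Derive the binary flags P0-P3, U2 and U3 from the orbit counts."""
    return IndicatorTable(
        labels=ot.labels,
        p0=ot.o0 > 0,
        p1=ot.o1 > 0,
        p2=ot.o2 > 0,
        p3=ot.o3 > 0,
        u2=ot.o2 == 1,
        u3=ot.o3 == 0,
    )


def graphlet_totals(ot: OrbitTable) -> tuple[int, int, int]:
    """Network-wide graphlet counts (G0, G1, G2) from the orbit sums.

    Every edge is touched twice at O0, every 3-path once at its center (O2)
    and every triangle three times at O3, hence the divisions below; a
    non-integral total would mean the orbit counts themselves are wrong.
    """
    s0, s2, s3 = int(ot.o0.sum()), int(ot.o2.sum()), int(ot.o3.sum())
    assert s0 % 2 == 0, "sum O0 must be even"
    assert s3 % 3 == 0, "sum O3 must be divisible by 3"
    return s0 // 2, s2, s3 // 3
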