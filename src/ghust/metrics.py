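"""The 12-dimensional graphlet topology fingerprint.

Every dimension is a ratio of orbit-count aggregates, grouped in four
categories:

* Global connectivity — rho1 (line surplus over a spanning tree), rho2
  (leaf rate), rho3 (leaf-base strength: mean neighbor degree of leaves).
* Hubs — rho4 (mean O2 over O2-touching nodes), rho5 (Spearman rank
  correlation between O1 and O2, mapped to [0, 1]).
* Strings — rho6 (share of O2-touchers that are string middles), rho7
  (characteristic string length, 1 - 1/mean).
* Triangles — rho8 (triangle share of 3-node graphlets), rho9 (triangle
  vertex sharing), rho10 (triangle pervasiveness), rho11 (isolated-triangle
  share), rho12 (mean degree of triangle vertices).

Six dimensions have an unscaled variant (rho'1, rho'3, rho'4, rho'5, rho'7,
rho'12); the scaled versions divide by the network's own max degree or max
O2 (or remap [-1, 1] to [0, 1] for rho5) so that vectors of networks of very
different size are directly comparable.

All numerators and denominators are integers, so every dimension except
rho5 is computed as an exact :class:`fractions.Fraction`; floats appear only
on serialization.  Denominators can legitimately be empty (a triangle-free
graph, a leafless cycle, ...): such dimensions receive a documented fill
value and the dimension name is recorded in ``degenerate_flags``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .graph_io import Graph
from .orbits import IndicatorTable, OrbitTable, count_orbits, indicators

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "GhustVector",
    "DIMENSION_NAMES",
    "spearman_rank_corr",
    "global_connectivity_dims",
    "hub_dims",
    "string_dims",
    "triangle_dims",
    "compute_ghust",
]

DIMENSION_NAMES = tuple(f"rho{k}" for k in range(1, 13))
RAW_NAMES = ("rho1_raw", "rho3_raw", "rho4_raw", "rho5_raw", "rho7_raw", "rho12_raw")

_RHO11_VARIANTS = ("degree2", "eq23", "no_o2")


@dataclass(frozen=True)
class MetricConfig:
    """Options for the fingerprint computation.

    Parameters
    ----------
    rho11_variant:
        How an "isolated triangle vertex" is identified.  ``degree2``
        (default) counts triangle vertices of degree exactly two, which is
        the only reading consistent with rho11 decreasing as triangles
        acquire outside connections; ``eq23`` counts triangle vertices with
        O2 = 1 and ``no_o2`` those with O2 = 0, both selectable for
        comparison.
    spearman_constant_fill:
        Raw correlation reported when O1 or O2 is constant across nodes
        (the rank correlation is then undefined).  The default 0 maps to
        rho5 = 0.5, i.e. "no association", and the dimension is flagged.
    """

    rho11_variant: str = "degree2"
    spearman_constant_fill: float = 0.0

    def __post_init__(self) -> None:
        if self.rho11_variant not in _RHO11_VARIANTS:
            raise ValueError(
                f"rho11_variant must be one of {_RHO11_VARIANTS}, got {self.rho11_variant!r}"
            )


@dataclass(frozen=True)
class GhustVector:
    """The 12 scaled dimensions plus raw variants and provenance.

    ``degenerate_flags`` lists the dimensions whose defining denominator was
    empty and which therefore carry their conventional fill value rather
    than a measured ratio.
    """

    rho1: Real
    rho2: Real
    rho3: Real
    rho4: Real
    rho5: Real
    rho6: Real
    rho7: Real
    rho8: Real
    rho9: Real
    rho10: Real
    rho11: Real
    rho12: Real
    rho1_raw: Real
    rho3_raw: Real
    rho4_raw: Real
    rho5_raw: Real
    rho7_raw: Real
    rho12_raw: Real
    degenerate_flags: frozenset[str] = field(default_factory=frozenset)
    n_strings: int = 0
    max_degree: int = 0
    max_o2: int = 0
    n_nodes: int = 0
    n_edges: int = 0

    def scaled(self) -> dict[str, Real]:
        """The 12 scaled dimensions as an ordered name -> value mapping."""
        return {name: getattr(self, name) for name in DIMENSION_NAMES}

    def as_array(self) -> np.ndarray:
        """The 12 scaled dimensions as a float vector (rho1..rho12)."""
        return np.array([float(getattr(self, n)) for n in DIMENSION_NAMES])

    def as_dict(self) -> dict:
        """Flat JSON-serializable record of every field."""
        out: dict = {"n_nodes": self.n_nodes, "n_edges": self.n_edges}
        for name in DIMENSION_NAMES + RAW_NAMES:
            out[name] = float(getattr(self, name))
        out["degenerate_flags"] = sorted(self.degenerate_flags)
        out["n_strings"] = self.n_strings
        out["max_degree"] = self.max_degree
        out["max_o2"] = self.max_o2
        return out


def spearman_rank_corr(
    x: Sequence[int] | np.ndarray,
    y: Sequence[int] | np.ndarray,
    constant_fill: float = 0.0,
) -> float:
    """Spearman rank correlation with average ranks for ties.

    Computed as the Pearson correlation of the midrank-transformed inputs.
    If either variable is constant its rank variance is zero and the
    correlation is undefined; ``constant_fill`` is returned instead (callers
    flag this case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return constant_fill
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _ratio(num: int, den: int) -> Fraction:
    return Fraction(int(num), int(den))


def global_connectivity_dims(
    ot: OrbitTable, it: IndicatorTable
) -> tuple[Real, Real, Real, Real, Real, set[str]]:
    """rho1 (line surplus), rho2 (leaf rate), rho3 (leaf-base strength).

    Returns ``(rho1, rho1_raw, rho2, rho3, rho3_raw, flags)``.
    """
    flags: set[str] = set()
    sum_p0 = int(it.p0.sum())
    sum_o0 = int(ot.o0.sum())
    # rho1: fraction of edges beyond the spanning-tree minimum (negative for
    # trees, since L0 is approximated by N rather than N - 1).
    rho1_raw = _ratio(sum_o0, 2 * sum_p0) - 1
    rho1 = 1 - _ratio(2 * sum_p0, sum_o0)

    not_tri = ~it.p3
    num2 = int((it.p2 & not_tri).sum())
    den2 = int((it.p1 & not_tri).sum())
    if den2 == 0:
        rho2 = Fraction(0)
        flags.add("rho2")
    else:
        rho2 = 1 - _ratio(num2, den2)

    leaf = it.p1 & ~it.p2 & ~it.p3
    n_leaf = int(leaf.sum())
    if n_leaf == 0:
        rho3_raw = Fraction(0)
        rho3 = Fraction(0)
        flags.add("rho3")
    else:
        rho3_raw = _ratio(int(ot.o1[leaf].sum()), n_leaf)
        rho3 = rho3_raw / int(ot.o0.max())
    return rho1, rho1_raw, rho2, rho3, rho3_raw, flags


def hub_dims(
    ot: OrbitTable,
    it: IndicatorTable,
    config: MetricConfig = MetricConfig(),
) -> tuple[Real, Real, Real, Real, set[str]]:
    """rho4 (hub coefficient) and rho5 (O1-O2 rank correlation).

    Returns ``(rho4, rho4_raw, rho5, rho5_raw, flags)``.
    """
    flags: set[str] = set()
    sum_p2 = int(it.p2.sum())
    if sum_p2 == 0:
        rho4_raw = Fraction(0)
        rho4 = Fraction(0)
        flags.add("rho4")
    else:
        rho4_raw = _ratio(int(ot.o2.sum()), sum_p2)
        rho4 = rho4_raw / int(ot.o2.max())

    constant = bool(np.all(ot.o1 == ot.o1[0]) or np.all(ot.o2 == ot.o2[0]))
    if constant:
        rho5_raw: Real = config.spearman_constant_fill
        flags.add("rho5")
    else:
        rho5_raw = spearman_rank_corr(ot.o1, ot.o2)
    rho5 = rho5_raw / 2 + Fraction(1, 2)
    if isinstance(rho5_raw, float) and float(rho5_raw) in (-1.0, 0.0, 1.0):
        # keep exactly representable correlations exact for rational tests
        rho5 = Fraction(int(rho5_raw)) / 2 + Fraction(1, 2)
        rho5_raw = Fraction(int(rho5_raw))
    return rho4, rho4_raw, rho5, rho5_raw, flags


def _string_components(g: Graph, middle: np.ndarray) -> tuple[int, int]:
    """Count connected components of the subgraph induced on string middles.

    Returns ``(n_components, n_cyclic)`` where a cyclic component is one
    with as many internal edges as nodes (a closed ring of degree-2 nodes,
    e.g. a cycle graph in its entirety) — it has no end nodes, which the
    string picture does not cover, so callers warn about it.
    """
    members = set(np.flatnonzero(middle).tolist())
    seen: set[int] = set()
    n_comp = n_cyclic = 0
    for start in members:
        if start in seen:
            continue
        n_comp += 1
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in g.adjacency[i]:
                if j in members and j not in seen:
                    seen.add(j)
                    stack.append(j)
        internal_edges = (
            sum(len(g.adjacency[i] & members) for i in comp) // 2
        )
        if internal_edges == len(comp):
            n_cyclic += 1
    return n_comp, n_cyclic


def string_dims(
    ot: OrbitTable, it: IndicatorTable, g: Graph
) -> tuple[Real, Real, Real, int, set[str]]:
    """rho6 (string-middle share) and rho7 (characteristic string length).

    A string middle is a degree-2 node outside any triangle (U2 = 1 and
    U3 = 1); a string is a connected run of such nodes.  Returns
    ``(rho6, rho7, rho7_raw, n_strings, flags)``.
    """
    flags: set[str] = set()
    middle = it.u2 & it.u3
    n_middle = int(middle.sum())
    sum_p2 = int(it.p2.sum())
    if sum_p2 == 0:
        rho6 = Fraction(0)
        flags.add("rho6")
    else:
        rho6 = _ratio(n_middle, sum_p2)

    if n_middle == 0:
        n_strings = 0
        rho7_raw = Fraction(0)
        rho7 = Fraction(0)
        flags.add("rho7")
    else:
        n_strings, n_cyclic = _string_components(g, middle)
        if n_cyclic:
            logger.warning(
                "%d string component(s) close into a cycle (no end nodes); "
                "each is counted as a single string",
                n_cyclic,
            )
        rho7_raw = _ratio(n_middle, n_strings)
        rho7 = 1 - _ratio(n_strings, n_middle)
    return rho6, rho7, rho7_raw, n_strings, flags


def triangle_dims(
    ot: OrbitTable,
    it: IndicatorTable,
    config: MetricConfig = MetricConfig(),
) -> tuple[Real, Real, Real, Real, Real, Real, set[str]]:
    """rho8-rho12: rate, concentration, pervasiveness, connectivity, degree.

    Returns ``(rho8, rho9, rho10, rho11, rho12, rho12_raw, flags)``.  In a
    triangle-free graph every denominator involving O3 or P3 is empty, so
    all five dimensions take fill value 0 and are flagged.
    """
    flags: set[str] = set()
    sum_o2 = int(ot.o2.sum())
    sum_o3 = int(ot.o3.sum())
    sum_p3 = int(it.p3.sum())

    if sum_o3 == 0:
        zero = Fraction(0)
        flags.update({"rho8", "rho9", "rho10", "rho11", "rho12"})
        return zero, zero, zero, zero, zero, zero, flags
    rho8 = _ratio(sum_o3, 3 * sum_o2 + sum_o3)

    rho9 = 1 - _ratio(sum_p3, sum_o3)
    rho10 = _ratio(sum_p3, int(it.p0.sum()))

    if config.rho11_variant == "degree2":
        isolated = it.p3 & (ot.o0 == 2)
    elif config.rho11_variant == "eq23":
        isolated = it.p3 & it.u2
    else:  # no_o2
        isolated = it.p3 & (ot.o2 == 0)
    rho11 = _ratio(int(isolated.sum()), sum_p3)

    rho12_raw = _ratio(int(ot.o0[it.p3].sum()), sum_p3)
    rho12 = rho12_raw / int(ot.o0.max())
    return rho8, rho9, rho10, rho11, rho12, rho12_raw, flags


def compute_ghust(
    g: Graph,
    config: MetricConfig = MetricConfig(),
    orbit_table: OrbitTable | None = None,
) -> GhustVector:
    """Compute the full 12-dimensional fingerprint of a connected graph.

    The graph must be connected with at least three nodes (smaller graphs
    have no 3-node graphlets at all).  Passing a precomputed ``orbit_table``
    skips the counting step.
    """
    if g.n_nodes < 3:
        raise ValueError(f"need at least 3 nodes, got {g.n_nodes}")
    ot = orbit_table if orbit_table is not None else count_orbits(g)
    it = indicators(ot)

    rho1, rho1_raw, rho2, rho3, rho3_raw, f_glob = global_connectivity_dims(ot, it)
    rho4, rho4_raw, rho5, rho5_raw, f_hub = hub_dims(ot, it, config)
    rho6, rho7, rho7_raw, n_strings, f_str = string_dims(ot, it, g)
    rho8, rho9, rho10, rho11, rho12, rho12_raw, f_tri = triangle_dims(ot, it, config)

    return GhustVector(
        rho1=rho1,
        rho2=rho2,
        rho3=rho3,
        rho4=rho4,
        rho5=rho5,
        rho6=rho6,
        rho7=rho7,
        rho8=rho8,
        rho9=rho9,
        rho10=rho10,
        rho11=rho11,
        rho12=rho12,
        rho1_raw=rho1_raw,
        rho3_raw=rho3_raw,
        rho4_raw=rho4_raw,
        rho5_raw=rho5_raw,
        rho7_raw=rho7_raw,
        rho12_raw=rho12_raw,
        degenerate_flags=frozenset(f_glob | f_hub | f_str | f_tri),
        n_strings=n_strings,
        max_degree=int(ot.o0.max()),
        max_o2=int(ot.o2.max()),
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
    )
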