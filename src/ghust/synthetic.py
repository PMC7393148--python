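"""Synthetic graph families with known or controlled fingerprint behavior.

Two layers:

* Canonical families (path, cycle, star, complete, bowtie chain) whose
  12 dimensions have exact closed forms, exposed by :func:`expected_ghust`
  as rational numbers — the test oracle for the metric layer.
* Random families (random trees, Erdős–Rényi, Barabási–Albert,
  Watts–Strogatz, grid lattices) and :func:`corpus`, which assembles small
  labeled collections emulating broad real-network classes: string-heavy
  infrastructure-like graphs, hub-dominated sparse graphs, and dense
  triangle-rich social-like graphs.

All randomness flows through an explicit integer seed; the same spec always
produces the identical graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

import networkx as nx
import numpy as np

from .graph_io import Graph, canonicalize

logger = logging.getLogger(__name__)

__all__ = [
    "FamilySpec",
    "LabeledGraph",
    "ExpectedGhust",
    "generate",
    "expected_ghust",
    "corpus",
    "PROFILES",
]

FAMILIES = (
    "path",
    "cycle",
    "star",
    "complete",
    "bowtie_chain",
    "random_tree",
    "erdos_renyi",
    "barabasi_albert",
    "watts_strogatz",
    "grid_lattice",
)

PROFILES = ("string_heavy", "hub_sparse", "triangle_dense", "mixed")


@dataclass(frozen=True)
class FamilySpec:
    """A graph family instance: family name, parameters and seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


class LabeledGraph(NamedTuple):
    name: str
    group: str
    graph: Graph


class ExpectedGhust(NamedTuple):
    """Closed-form fingerprint entries for a canonical family.

    ``values`` maps dimension names (scaled and raw) to exact rationals,
    including the conventional fill for degenerate dimensions; ``degenerate``
    names the dimensions expected to carry a fill rather than a measurement.
    """

    values: dict[str, Fraction]
    degenerate: frozenset[str]


def _bowtie_chain(k: int) -> nx.Graph:
    """k triangles chained so consecutive triangles share one vertex.

    Nodes 0..2k; triangle i spans (2i-2, 2i-1, 2i).  k=2 is the classic
    5-node bowtie.
    """
    if k < 1:
        raise ValueError("bowtie_chain needs k >= 1")
    g = nx.Graph()
    for i in range(1, k + 1):
        a, b, c = 2 * i - 2, 2 * i - 1, 2 * i
        g.add_edges_from([(a, b), (b, c), (a, c)])
    return g


def generate(spec: FamilySpec) -> Graph:
    """Generate the connected simple graph described by ``spec``.

    Stochastic families draw from ``numpy``-independent ``networkx``
    generators seeded with ``spec.seed``.  Families that can come out
    disconnected (Erdős–Rényi, grids are always connected) are resampled up
    to 100 times; if still disconnected the largest component is kept and a
    log line records the fallback.
    """
    p = spec.params
    fam = spec.family
    if fam == "path":
        gx = nx.path_graph(int(p["n"]))
    elif fam == "cycle":
        gx = nx.cycle_graph(int(p["n"]))
    elif fam == "star":
        gx = nx.star_graph(int(p["n_leaves"]))
    elif fam == "complete":
        gx = nx.complete_graph(int(p["n"]))
    elif fam == "bowtie_chain":
        gx = _bowtie_chain(int(p["k"]))
    elif fam == "random_tree":
        gx = nx.random_labeled_tree(int(p["n"]), seed=spec.seed)
    elif fam == "erdos_renyi":
        n, prob = int(p["n"]), float(p["p"])
        if not 0 < prob <= 1:
            raise ValueError("erdos_renyi requires p in (0, 1]")
        gx = None
        for attempt in range(100):
            cand = nx.gnp_random_graph(n, prob, seed=spec.seed + attempt)
            if nx.is_connected(cand):
                gx = cand
                break
        if gx is None:
            gx = nx.gnp_random_graph(n, prob, seed=spec.seed)
            logger.warning(
                "erdos_renyi(n=%d, p=%.3g, seed=%d) stayed disconnected after "
                "100 attempts; keeping largest component",
                n,
                prob,
                spec.seed,
            )
            return canonicalize(Graph.from_networkx(gx), "largest_component")
    elif fam == "barabasi_albert":
        m = int(p["m"])
        if m < 1:
            raise ValueError("barabasi_albert requires m >= 1")
        gx = nx.barabasi_albert_graph(int(p["n"]), m, seed=spec.seed)
    elif fam == "watts_strogatz":
        gx = nx.connected_watts_strogatz_graph(
            int(p["n"]), int(p["k"]), float(p["p"]), seed=spec.seed
        )
    elif fam == "grid_lattice":
        gx = nx.grid_2d_graph(int(p["rows"]), int(p["cols"]))
        gx = nx.convert_node_labels_to_integers(gx, ordering="sorted")
    else:  # pragma: no cover - guarded by FamilySpec
        raise ValueError(fam)
    return Graph.from_networkx(gx)


# -- closed forms ----------------------------------------------------------


def _zeros(names: tuple[str, ...]) -> dict[str, Fraction]:
    return {n: Fraction(0) for n in names}

_TRI_NAMES = ("rho8", "rho9", "rho10", "rho11", "rho12", "rho12_raw")


def _expected_path(n: int) -> ExpectedGhust:
    if n < 3:
        raise ValueError("path closed forms need n >= 3")
    v: dict[str, Fraction] = {}
    v["rho1"] = Fraction(-1, n - 1)
    v["rho1_raw"] = Fraction(-1, n)
    sum_p1 = 2 if n == 3 else n  # for n=3 the center has O1 = 0
    v["rho2"] = 1 - Fraction(n - 2, sum_p1)
    v["rho3_raw"] = Fraction(1)  # each end's neighbor has degree 2
    v["rho3"] = Fraction(1, 2)
    v["rho4_raw"] = Fraction(1)
    v["rho4"] = Fraction(1)
    degenerate = set(_TRI_NAMES[:5])
    v.update(_zeros(_TRI_NAMES))
    if n == 3:
        v["rho5_raw"] = Fraction(-1)  # O1 = (1,0,1) vs O2 = (0,1,0)
        v["rho5"] = Fraction(0)
    elif n == 4:
        v["rho5_raw"] = Fraction(0)
        v["rho5"] = Fraction(1, 2)
        degenerate.add("rho5")
    # n >= 5: rank pattern has no simple closed form; omitted
    v["rho6"] = Fraction(1)
    v["rho7_raw"] = Fraction(n - 2)
    v["rho7"] = 1 - Fraction(1, n - 2)
    return ExpectedGhust(v, frozenset(degenerate))


def _expected_cycle(n: int) -> ExpectedGhust:
    if n < 4:
        raise ValueError("cycle closed forms need n >= 4 (C3 is the complete K3)")
    v: dict[str, Fraction] = {
        "rho1": Fraction(0),
        "rho1_raw": Fraction(0),
        "rho2": Fraction(0),
        "rho3": Fraction(0),
        "rho3_raw": Fraction(0),
        "rho4": Fraction(1),
        "rho4_raw": Fraction(1),
        "rho5": Fraction(1, 2),
        "rho5_raw": Fraction(0),
        "rho6": Fraction(1),
        "rho7_raw": Fraction(n),
        "rho7": 1 - Fraction(1, n),
    }
    v.update(_zeros(_TRI_NAMES))
    return ExpectedGhust(v, frozenset({"rho3", "rho5", *_TRI_NAMES[:5]}))


def _expected_star(m: int) -> ExpectedGhust:
    if m < 3:
        raise ValueError("star closed forms need >= 3 leaves")
    v: dict[str, Fraction] = {
        "rho1": Fraction(-1, m),
        "rho1_raw": Fraction(-1, m + 1),
        "rho2": 1 - Fraction(1, m),
        "rho3_raw": Fraction(m - 1),
        "rho3": Fraction(m - 1, m),
        "rho4_raw": Fraction(m * (m - 1), 2),
        "rho4": Fraction(1),
        "rho5_raw": Fraction(-1),  # the hub is the unique O2-toucher, leaves carry O1
        "rho5": Fraction(0),
        "rho6": Fraction(0),
        "rho7": Fraction(0),
        "rho7_raw": Fraction(0),
    }
    v.update(_zeros(_TRI_NAMES))
    return ExpectedGhust(v, frozenset({"rho7", *_TRI_NAMES[:5]}))


def _expected_complete(n: int) -> ExpectedGhust:
    if n < 3:
        raise ValueError("complete closed forms need n >= 3")
    t = (n - 1) * (n - 2) // 2  # triangles through each node
    v: dict[str, Fraction] = {
        "rho1": 1 - Fraction(2, n - 1),
        "rho1_raw": Fraction(n - 3, 2),
        "rho2": Fraction(0),
        "rho3": Fraction(0),
        "rho3_raw": Fraction(0),
        "rho4": Fraction(0),
        "rho4_raw": Fraction(0),
        "rho5": Fraction(1, 2),
        "rho5_raw": Fraction(0),
        "rho6": Fraction(0),
        "rho7": Fraction(0),
        "rho7_raw": Fraction(0),
        "rho8": Fraction(1),
        "rho9": 1 - Fraction(1, t),
        "rho10": Fraction(1),
        "rho11": Fraction(1) if n == 3 else Fraction(0),
        "rho12_raw": Fraction(n - 1),
        "rho12": Fraction(1),
    }
    return ExpectedGhust(
        v, frozenset({"rho2", "rho3", "rho4", "rho5", "rho6", "rho7"})
    )


def _expected_bowtie_chain(k: int) -> ExpectedGhust:
    if k < 2:
        raise ValueError("bowtie_chain closed forms need k >= 2 (k=1 is K3)")
    n = 2 * k + 1
    v: dict[str, Fraction] = {
        "rho1": Fraction(k - 1, 3 * k),
        "rho1_raw": Fraction(k - 1, n),
        "rho2": Fraction(0),
        "rho3": Fraction(0),
        "rho3_raw": Fraction(0),
        "rho4_raw": Fraction(4),
        "rho4": Fraction(1),
        "rho6": Fraction(0),
        "rho7": Fraction(0),
        "rho7_raw": Fraction(0),
        "rho8": Fraction(k, 5 * k - 4),
        "rho9": 1 - Fraction(n, 3 * k),
        "rho10": Fraction(1),
        "rho11": Fraction(k + 2, n),
        "rho12_raw": Fraction(6 * k, n),
        "rho12": Fraction(3 * k, 2 * n),
    }
    degenerate = {"rho2", "rho3", "rho7"}
    if k == 2:
        # O2 is nonzero only on the shared vertex, O1 only elsewhere: the
        # rank variables are perfectly anti-aligned.
        v["rho5_raw"] = Fraction(-1)
        v["rho5"] = Fraction(0)
    return ExpectedGhust(v, frozenset(degenerate))


def expected_ghust(spec: FamilySpec) -> ExpectedGhust:
    """Exact fingerprint values for a canonical family, where closed forms exist.

    Supported families: path, cycle, star, complete, bowtie_chain.  Entries
    without a simple closed form (e.g. rho5 of long paths) are omitted from
    ``values``; degenerate dimensions are present with their fill value and
    listed in ``degenerate``.
    """
    p = spec.params
    if spec.family == "path":
        return _expected_path(int(p["n"]))
    if spec.family == "cycle":
        return _expected_cycle(int(p["n"]))
    if spec.family == "star":
        return _expected_star(int(p["n_leaves"]))
    if spec.family == "complete":
        return _expected_complete(int(p["n"]))
    if spec.family == "bowtie_chain":
        return _expected_bowtie_chain(int(p["k"]))
    raise ValueError(f"no closed forms for family {spec.family!r}")


# -- corpus profiles -------------------------------------------------------


def _string_heavy(rng: np.random.Generator, seed: int) -> Graph:
    """A random tree or a sparse grid with pendant paths: string-rich, no hubs.

    Emulates road- and power-grid-like infrastructure topology.
    """
    if rng.random() < 0.5:
        n = int(rng.integers(40, 81))
        return generate(FamilySpec("random_tree", {"n": n}, seed))
    # narrow mesh core with long pendant chains hanging off it, the way
    # road and distribution networks string consumers along corridors
    rows = int(rng.integers(2, 4))
    cols = int(rng.integers(5, 9))
    g = generate(FamilySpec("grid_lattice", {"rows": rows, "cols": cols}, seed))
    gx = g.to_networkx()
    nodes = sorted(gx.nodes())
    n_paths = int(rng.integers(5, 10))
    nxt = len(nodes)
    for _ in range(n_paths):
        anchor = nodes[int(rng.integers(0, len(nodes)))]
        length = int(rng.integers(3, 9))
        prev = anchor
        for _ in range(length):
            gx.add_edge(prev, f"p{nxt}")
            prev = f"p{nxt}"
            nxt += 1
    return Graph.from_networkx(gx)


def _hub_sparse(rng: np.random.Generator, seed: int) -> Graph:
    """Preferential-attachment graph with m in {1, 2}: hub-dominated, sparse.

    Emulates autonomous-system / router-level internet topology.
    """
    n = int(rng.integers(60, 121))
    m = int(rng.integers(1, 3))
    return generate(FamilySpec("barabasi_albert", {"n": n, "m": m}, seed))


def _triangle_dense(rng: np.random.Generator, seed: int) -> Graph:
    """Small-world ring or dense ER graph: triangle-rich, clustered.

    Emulates social/friendship network topology.
    """
    if rng.random() < 0.5:
        n = int(rng.integers(40, 71))
        k = int(rng.choice([6, 8]))
        return generate(FamilySpec("watts_strogatz", {"n": n, "k": k, "p": 0.05}, seed))
    n = int(rng.integers(30, 51))
    return generate(FamilySpec("erdos_renyi", {"n": n, "p": 0.3}, seed))


def corpus(profile: str, count: int, seed: int) -> list[LabeledGraph]:
    """Generate ``count`` labeled graphs drawn from a topology profile.

    ``mixed`` cycles through the three pure profiles, emulating a collection
    of networks of heterogeneous origin.  Identical arguments always return
    the identical corpus.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {PROFILES}")
    if count < 1:
        raise ValueError("count must be >= 1")
    makers = {
        "string_heavy": _string_heavy,
        "hub_sparse": _hub_sparse,
        "triangle_dense": _triangle_dense,
    }
    out: list[LabeledGraph] = []
    for i in range(count):
        sub_seed = seed + 7919 * i  # distinct, reproducible per-item seeds
        rng = np.random.default_rng(sub_seed)
        if profile == "mixed":
            maker = makers[("string_heavy", "hub_sparse", "triangle_dense")[i % 3]]
        else:
            maker = makers[profile]
        g = maker(rng, sub_seed)
        out.append(LabeledGraph(f"{profile}_{i:03d}", profile, g))
    return out
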