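"""The 12 fingerprint dimensions: exact values, conventions, invariants."""

from fractions import Fraction as F

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ghust import (
    DIMENSION_NAMES,
    FamilySpec,
    MetricConfig,
    compute_ghust,
    count_orbits,
    generate,
    indicators,
    spearman_rank_corr,
)
from ghust.metrics import (
    global_connectivity_dims,
    hub_dims,
    string_dims,
    triangle_dims,
)


def tables(g):
    ot = count_orbits(g)
    return ot, indicators(ot)


# -- global connectivity ---------------------------------------------------


def test_global_dims_path(p4):
    rho1, rho1_raw, rho2, rho3, rho3_raw, flags = global_connectivity_dims(*tables(p4))
    assert (rho1, rho1_raw, rho2, rho3_raw, rho3) == (F(-1, 3), F(-1, 4), F(1, 2), 1, F(1, 2))
    assert not flags


def test_global_dims_cycle(c10):
    rho1, _, rho2, rho3, _, flags = global_connectivity_dims(*tables(c10))
    assert rho1 == 0 and rho2 == 0
    assert rho3 == 0 and flags == {"rho3"}  # a cycle has no leaf nodes


def test_global_dims_star(star4):
    rho1, _, rho2, rho3, rho3_raw, flags = global_connectivity_dims(*tables(star4))
    assert (rho1, rho2, rho3_raw, rho3) == (F(-1, 4), F(3, 4), 3, F(3, 4))
    assert not flags


# -- hubs ------------------------------------------------------------------


def test_hub_dims_star(star4):
    rho4, rho4_raw, rho5, rho5_raw, flags = hub_dims(*tables(star4))
    assert (rho4_raw, rho4) == (6, 1)
    # O1 and O2 are perfectly anti-monotone across hub and leaves
    assert rho5_raw == -1 and rho5 == 0
    assert not flags


def test_hub_dims_constant_rank_convention(c10, p4):
    for g in (c10, p4):
        rho4, _, rho5, rho5_raw, flags = hub_dims(*tables(g))
        assert rho4 == 1
        assert rho5 == F(1, 2) and rho5_raw == 0
        assert "rho5" in flags


# -- strings ---------------------------------------------------------------


def test_string_dims_path(p4):
    rho6, rho7, rho7_raw, n_strings, flags = string_dims(*tables(p4), p4)
    assert (rho6, rho7_raw, rho7, n_strings) == (1, 2, F(1, 2), 1)
    assert not flags


def test_string_dims_cycle_counts_one_endless_string(c10):
    rho6, rho7, rho7_raw, n_strings, flags = string_dims(*tables(c10), c10)
    assert (rho6, n_strings, rho7) == (1, 1, F(9, 10))
    assert not flags


def test_string_dims_degenerate_on_complete(k4):
    rho6, rho7, _, n_strings, flags = string_dims(*tables(k4), k4)
    assert rho6 == 0 and rho7 == 0 and n_strings == 0
    assert flags == {"rho6", "rho7"}


def test_multiple_strings_are_separated():
    # two pendant paths hanging off a K4: two strings of middles, lengths 2 and 3
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges += [(0, 10), (10, 11), (11, 12)]  # middles 10, 11
    edges += [(1, 20), (20, 21), (21, 22), (22, 23)]  # middles 20, 21, 22
    from ghust import Graph

    g = Graph.from_edges([(str(u), str(v)) for u, v in edges])
    rho6, rho7, rho7_raw, n_strings, flags = string_dims(*tables(g), g)
    assert n_strings == 2
    assert rho7_raw == F(5, 2)
    assert rho7 == 1 - F(2, 5)


# -- triangles -------------------------------------------------------------


def test_triangle_dims_k3(triangle):
    rho8, rho9, rho10, rho11, rho12, rho12_raw, flags = triangle_dims(*tables(triangle))
    assert (rho8, rho9, rho10, rho11, rho12_raw, rho12) == (1, 0, 1, 1, 2, 1)
    assert not flags


def test_triangle_dims_k4(k4):
    rho8, rho9, rho10, rho11, rho12, _, flags = triangle_dims(*tables(k4))
    assert (rho8, rho9, rho10, rho11, rho12) == (1, F(2, 3), 1, 0, 1)


def test_triangle_dims_bowtie(bowtie):
    rho8, rho9, rho10, rho11, rho12, rho12_raw, flags = triangle_dims(*tables(bowtie))
    assert (rho8, rho9, rho10, rho11) == (F(1, 3), F(1, 6), 1, F(4, 5))
    assert rho12_raw == F(12, 5) and rho12 == F(3, 5)


def test_triangle_dims_zero_and_flagged_on_trees():
    g = generate(FamilySpec("random_tree", {"n": 25}, seed=9))
    vals = triangle_dims(*tables(g))
    assert all(v == 0 for v in vals[:-1])
    assert vals[-1] == {"rho8", "rho9", "rho10", "rho11", "rho12"}


@pytest.mark.parametrize(
    "variant,k3_val,k4_val,bowtie_val",
    [
        ("degree2", 1, 0, F(4, 5)),  # triangle vertices with exactly 2 connections
        ("eq23", 0, 0, 0),  # literal O2 = 1 reading
        ("no_o2", 1, 1, F(4, 5)),  # O2 = 0 reading
    ],
)
def test_rho11_variants(triangle, k4, bowtie, variant, k3_val, k4_val, bowtie_val):
    cfg = MetricConfig(rho11_variant=variant)
    assert triangle_dims(*tables(triangle), cfg)[3] == k3_val
    assert triangle_dims(*tables(k4), cfg)[3] == k4_val
    assert triangle_dims(*tables(bowtie), cfg)[3] == bowtie_val


# -- spearman sub-oracle ---------------------------------------------------


def naive_spearman(x, y):
    """Independent oracle: explicit average ranks + explicit Pearson formula."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def test_spearman_examples():
    assert spearman_rank_corr([1, 2, 3], [3, 2, 1]) == -1
    assert spearman_rank_corr([1, 2, 3], [10, 20, 30]) == 1
    assert spearman_rank_corr([0, 3, 3, 3, 3], [6, 0, 0, 0, 0]) == pytest.approx(-1)


def test_spearman_errors_and_convention():
    with pytest.raises(ValueError):
        spearman_rank_corr([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman_rank_corr([1], [1])
    assert spearman_rank_corr([5, 5, 5], [1, 2, 3]) == 0.0


@given(
    st.lists(
        st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=2, max_size=40
    )
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_spearman_matches_naive_and_scipy(pairs):
    x = [a for a, _ in pairs]
    y = [b for _, b in pairs]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return
    ours = spearman_rank_corr(x, y)
    assert ours == pytest.approx(naive_spearman(x, y), abs=1e-12)
    assert ours == pytest.approx(spearmanr(x, y).statistic, abs=1e-10)


# -- aggregate -------------------------------------------------------------


def test_compute_ghust_rejects_tiny_graphs():
    from ghust import Graph

    with pytest.raises(ValueError):
        compute_ghust(Graph.from_edges([("a", "b")]))


def test_compute_ghust_deterministic():
    g = generate(FamilySpec("erdos_renyi", {"n": 40, "p": 0.2}, seed=11))
    v1, v2 = compute_ghust(g), compute_ghust(g)
    assert v1 == v2


def test_dimensions_are_exact_rationals(bowtie):
    v = compute_ghust(bowtie)
    for name in DIMENSION_NAMES:
        if name == "rho5":
            continue  # rank correlation involves a square root
        assert isinstance(getattr(v, name), F), name


def test_range_invariants_on_random_graphs():
    specs = [
        FamilySpec("erdos_renyi", {"n": 30, "p": p}, seed=s)
        for p in (0.07, 0.15, 0.3)
        for s in range(5)
    ] + [
        FamilySpec("barabasi_albert", {"n": 40, "m": m}, seed=s)
        for m in (1, 2, 3)
        for s in range(5)
    ]
    for spec in specs:
        g = generate(spec)
        v = compute_ghust(g)
        for name in DIMENSION_NAMES[1:]:
            val = float(getattr(v, name))
            assert 0 <= val <= 1, (spec, name, val)
        assert float(v.rho1) >= -1 / (g.n_nodes - 1)
        assert float(v.rho1) < 1


def test_cycle_vectors_size_independent_except_rho7():
    v10 = compute_ghust(generate(FamilySpec("cycle", {"n": 10})))
    v100 = compute_ghust(generate(FamilySpec("cycle", {"n": 100})))
    for name in DIMENSION_NAMES:
        if name == "rho7":
            continue
        assert getattr(v10, name) == getattr(v100, name), name
    assert (v10.rho7, v100.rho7) == (F(9, 10), F(99, 100))


def test_middle_node_partition_identity():
    # string middles plus non-middle O2-touchers account for every O2-toucher
    for seed in range(5):
        g = generate(FamilySpec("watts_strogatz", {"n": 40, "k": 4, "p": 0.3}, seed=seed))
        ot, it = tables(g)
        middle = it.u2 & it.u3
        non_middle = it.p2 & ~middle
        assert int(middle.sum()) + int(non_middle.sum()) == int(it.p2.sum())
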