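"""The multi-target level sweep: edge-count bounds, optionality, pruning."""

import itertools
import logging
from math import comb

import networkx as nx
import pytest

import nild.graph_core as gc
from nild.baselines import enum_optimal
from nild.oisa import (
    EoreState,
    eore_prune,
    global_edge_lower_bound,
    lcc_upper_bound,
    min_edges_for_lcc,
    oisa,
    optionality,
    ponf_select,
    target_lcc_levels,
)
from nild.problem import Constraints, NildInstance, check_tau, objective
from nild.synthetic import make_instance

VACUOUS = dict(omega_b=-1.0, omega_c=-1.0, omega_d=0)


# ---------------------------------------------------------------------------
# minimum intervention edges for a targeted clustering level


@pytest.mark.parametrize(
    "lcc, degree, level, expected",
    [
        (0.3, 5, 0.3, 0),  # already at the level
        (0.0, 0, 0.5, 0),
        (1.0, 2, 0.5, 1),  # (3)(2) = 6 >= 2/0.5
        (1.0, 3, 0.2, 3),  # need (3+k)(2+k) >= 30
    ],
)
def test_min_edges_examples(lcc, degree, level, expected):
    assert min_edges_for_lcc(lcc, degree, level) == expected


def test_min_edges_rejects_nonpositive_level():
    with pytest.raises(ValueError, match="level"):
        min_edges_for_lcc(0.5, 3, 0.0)


def test_min_edges_matches_linear_scan_oracle():
    """Closed-form + adjustment equals the smallest k found by brute scan."""
    for degree in range(0, 9):
        for num in range(0, comb(degree, 2) + 1 if degree >= 2 else 1):
            lcc = num / comb(degree, 2) if degree >= 2 else 0.0
            for level in (0.05, 1 / 3, 0.5, 0.9):
                lhs = lcc * degree * (degree - 1)
                k = 0
                while lhs > level * (degree + k) * (degree + k - 1):
                    k += 1
                assert min_edges_for_lcc(lcc, degree, level) == k


def test_global_edge_lower_bound_pairs_targets():
    # disjoint triangles: each picked vertex has LCC 1, degree 2 -> needs one
    # edge at level 0.5; one edge can serve two targets
    def tri_instance(n_tris, **kw):
        g = nx.disjoint_union_all([nx.complete_graph(3)] * n_tris)
        targets = [3 * i for i in range(n_tris)]
        return NildInstance(g, targets, Constraints(**kw))

    assert global_edge_lower_bound(tri_instance(2, k=1, **VACUOUS), 0.5) == 1
    assert global_edge_lower_bound(tri_instance(3, k=1, **VACUOUS), 0.5) == 2
    assert global_edge_lower_bound(tri_instance(2, k=1, **VACUOUS), 1.0) == 0
    # the degree floor enters the per-target need
    assert global_edge_lower_bound(tri_instance(2, k=1, omega_d=4), 1.0) == 2


# ---------------------------------------------------------------------------
# the targeted-LCC schedule


def fan_graph():
    """Target t fanned to n1..n4 with a path among the neighbors and pendant
    tails: LCC(t) = 1/2, max LCC in G = 2/3 (nodes n2, n3), degree(t) = 4."""
    return nx.Graph([
        ("t", "n1"), ("t", "n2"), ("t", "n3"), ("t", "n4"),
        ("n1", "n2"), ("n2", "n3"), ("n3", "n4"),
        ("n1", "p1"), ("n4", "p4"),
    ])


def test_level_schedule_arithmetic():
    inst = NildInstance(fan_graph(), ["t"], Constraints(k=1, **VACUOUS))
    assert inst.baseline_lccs["t"] == pytest.approx(1 / 2)
    assert max(inst.baseline_lccs.values()) == pytest.approx(2 / 3)
    # d_cap = 4 -> C(4,2) = 6; emit j/6 while below the scope's max LCC
    assert target_lcc_levels(inst) == pytest.approx([1 / 6, 2 / 6, 3 / 6])
    assert target_lcc_levels(inst, scope="targets") == pytest.approx([1 / 6, 2 / 6])


def test_level_schedule_empty_cases(caplog):
    g = nx.Graph([("t", 1), (1, 2), (2, 3)])  # degree(t) = 1 -> no level basis
    inst = NildInstance(g, ["t"], Constraints(k=1, **VACUOUS))
    with caplog.at_level(logging.WARNING, logger="nild.oisa"):
        assert target_lcc_levels(inst) == []
    assert any("no targeted-LCC level" in r.message for r in caplog.records)
    star = nx.star_graph(3)  # no triangles anywhere: max LCC 0
    inst2 = NildInstance(star, [0], Constraints(k=1, **VACUOUS))
    assert target_lcc_levels(inst2) == []


# ---------------------------------------------------------------------------
# the closed-form LCC ceiling


@pytest.mark.parametrize(
    "degree, tri, budget, expected",
    [
        (4, 3, 0, 0.5),  # budget 0 collapses to the current LCC
        (2, 1, 1, 2.0),  # raw value exceeds 1: splits give 3/3 and 2/1
        (3, 0, 2, 0.7),  # splits: 2/3, 4/6, 7/10
    ],
)
def test_lcc_upper_bound_examples(degree, tri, budget, expected):
    assert lcc_upper_bound(degree, tri, budget) == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(6))
def test_lcc_upper_bound_exhaustive_soundness(seed):
    """Every node's LCC after every <= 2-edge addition stays under the bound."""
    g = nx.gnp_random_graph(8, 0.4, seed=seed)
    base = gc.all_metrics(g)
    non_edges = [gc.canonical_edge(e) for e in nx.non_edges(g)]
    for k in (1, 2):
        bounds = {v: lcc_upper_bound(g.degree(v), base[v].triangle_edges, k) for v in g}
        for F in itertools.combinations(non_edges, k):
            _, post = gc.apply_edges(g, base, F)
            for v in g:
                assert post[v].lcc <= bounds[v] + 1e-12


# ---------------------------------------------------------------------------
# optionality and selection


def optionality_fixture():
    """t with one risky 2-hop target (shared neighbor c would jump 0 -> 1),
    and one safe 4-hop target."""
    g = nx.Graph([("t", "c"), ("c", "u2"), ("t", "x"), ("x", "y"), ("y", "z"), ("z", "u4")])
    return NildInstance(g, ["t", "u2", "u4"], Constraints(k=2, tau=0.5, **VACUOUS))


def test_optionality_counts_safe_partners():
    inst = optionality_fixture()
    opts = optionality(inst, "t", inst.empty_plan())
    assert opts.options == ("u4",)
    assert opts.optionality == 1


def test_optionality_all_far_targets():
    g = nx.Graph([("a", 1), (1, 2), (2, 3), (3, "b"), ("b", 4), (4, 5), (5, 6), (6, "c")])
    inst = NildInstance(g, ["a", "b", "c"], Constraints(k=1, tau=0.0, **VACUOUS))
    assert optionality(inst, "a", inst.empty_plan()).optionality == 2


def test_optionality_excludes_neighbors(triangle):
    inst = NildInstance(triangle, [0, 1, 2], Constraints(k=1, tau=1.0, **VACUOUS))
    assert optionality(inst, 0, inst.empty_plan()).optionality == 0


def test_ponf_prefers_smallest_optionality_on_ties():
    # Two LCC-1 targets A and B tied at the top; B has fewer safe partners
    # (its 2-hop partner Z2 is blocked at tau = 0), so PONF must pick m = B.
    g = nx.Graph()
    g.add_edges_from([("A", "a2"), ("A", "a3"), ("a2", "a3"), ("A", "w0")])
    g.add_edges_from([("B", "b2"), ("B", "b3"), ("b2", "b3")])
    g.add_edges_from([("B", "s"), ("s", "Z2")])  # Z2 two hops from B via s
    g.add_edges_from([("w0", "w1"), ("w1", "Z1"), ("Z1", "w2"), ("w2", "b3")])
    inst = NildInstance(
        g, ["A", "B", "Z1", "Z2"], Constraints(k=1, tau=0.0, **VACUOUS)
    )
    assert inst.baseline_lccs["A"] == inst.baseline_lccs["B"] == pytest.approx(1 / 3)
    o_a = optionality(inst, "A", inst.empty_plan()).optionality
    o_b = optionality(inst, "B", inst.empty_plan()).optionality
    assert o_b < o_a  # Z2 is unsafe for B but fine (far) for A
    m, u = ponf_select(inst, inst.empty_plan())
    assert m == "B"
    assert u == "A"  # the largest-LCC member of B's option set


def test_ponf_returns_none_without_options():
    g = nx.complete_graph(4)
    inst = NildInstance(g, [0, 1], Constraints(k=1, tau=1.0, **VACUOUS))
    assert ponf_select(inst, inst.empty_plan()) is None


def test_eore_prune_arithmetic():
    g = nx.disjoint_union_all([nx.complete_graph(3)] * 2)
    inst = NildInstance(g, [0, 3], Constraints(k=1, tau=1.0, **VACUOUS))
    plan = inst.empty_plan()
    state = EoreState(1, 0.5, 2, {0: 1, 3: 1}, 1)
    assert not eore_prune(inst, state, plan)  # k - 0 + 0 >= 1 for both
    state_big = EoreState(1, 0.1, 2, {0: 3, 3: 0}, 2)
    assert eore_prune(inst, state_big, plan)  # target 0 needs 3, budget is 1


# ---------------------------------------------------------------------------
# the full sweep


def test_oisa_star_single_target_returns_empty_plan():
    g = nx.star_graph(4)
    g.add_edge(1, 2)  # give the graph a triangle so a level exists
    inst = NildInstance(g, [0], Constraints(k=2, tau=1.0, **VACUOUS))
    plan = oisa(inst)
    assert plan.edges == ()


def test_oisa_bounded_by_enum_and_tau_feasible():
    for seed in range(15):
        inst = make_instance(
            "multi", 10 + seed % 3, "erdos_renyi", seed=seed,
            overrides=Constraints(k=1 + seed % 3, tau=[0.1, 0.3, 1.0][seed % 3], **VACUOUS),
        )
        plan = oisa(inst)
        assert check_tau(inst, plan)[0]
        assert objective(inst, plan) >= objective(inst, enum_optimal(inst)) - 1e-12
        assert objective(inst, plan) <= objective(inst, inst.empty_plan()) + 1e-12


def test_oisa_alc_toggle_is_exact():
    for seed in range(8):
        inst = make_instance(
            "multi", 14, "erdos_renyi", seed=seed,
            overrides=Constraints(k=3, tau=0.2, **VACUOUS),
        )
        assert oisa(inst, use_alc=True).edges == oisa(inst, use_alc=False).edges


def test_oisa_deterministic():
    inst = make_instance(
        "multi", 15, "erdos_renyi", seed=9,
        overrides=Constraints(k=3, tau=0.15, **VACUOUS),
    )
    assert oisa(inst).edges == oisa(inst).edges
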