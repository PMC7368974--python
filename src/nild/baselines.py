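"""Comparison algorithms: BUM, SIM, and the exhaustive ENUM optimum.

All three draw intervention edges from the same universe as OISA — pairs of
non-adjacent targets — so head-to-head objective comparisons are
apples-to-apples.  BUM greedily connects the two largest-LCC targets that stay
degradation-safe; SIM connects the largest-LCC target to the farthest safe
target (distance shrinks the set of common neighbors whose LCC could rise);
ENUM exhausts every edge set up to the budget and is the ground-truth optimum
used by the test oracles.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb, inf
from typing import List, Optional, Tuple

from . import graph_core as gc
from .crpd import miss_score, miss_weights
from .graph_core import Edge, Node
from .oisa import _omega_unmet
from .problem import InterventionPlan, NildInstance, edge_addition_feasible

logger = logging.getLogger(__name__)

__all__ = ["bum", "sim", "enum_optimal", "EnumerationCapError"]


def _greedy_pair_loop(instance: NildInstance, rank: str) -> InterventionPlan:
    """Shared engine for BUM/SIM: k rounds of (max-LCC target m, ranked u)."""
    plan = instance.empty_plan()
    metrics = dict(instance.baseline_metrics)
    for _ in range(instance.constraints.k):
        g = plan.post_graph
        lccs = {t: metrics[t].lcc for t in instance.targets}
        m = min(instance.targets, key=lambda t: (-lccs[t], t))
        pool = [u for u in instance.targets if u != m and not g.has_edge(m, u)]
        if not pool:
            break
        if _omega_unmet(instance, g, m):
            w = miss_weights(g, m, instance.constraints)
            scores = {u: miss_score(g, u, w) for u in pool}
            pool.sort(key=lambda u: (-scores[u], -lccs[u], u))
        elif rank == "lcc":
            pool.sort(key=lambda u: (-lccs[u], u))
        else:  # rank == "hops": farthest first, infinity outranks all finite
            dist = {u: gc.hop_distance(g, m, u) for u in pool}
            pool.sort(
                key=lambda u: (
                    0 if dist[u] == inf else 1,
                    -dist[u] if dist[u] != inf else 0,
                    -lccs[u],
                    u,
                )
            )
        chosen: Optional[Node] = None
        for u in pool:
            if edge_addition_feasible(instance, plan, metrics, (m, u)):
                chosen = u
                break
        if chosen is None:
            logger.warning("no degradation-safe partner for %r; stopping early", m)
            break
        pre = plan.post_graph
        plan = plan.extended((m, chosen), algorithm=rank_name(rank))
        metrics = gc.update_lccs(pre, metrics, gc.canonical_edge((m, chosen)))
    return plan


def rank_name(rank: str) -> str:
    return {"lcc": "bum", "hops": "sim"}[rank]


def bum(instance: NildInstance) -> InterventionPlan:
    """Budget-utility maximization: pair the two largest-LCC targets each round."""
    return _greedy_pair_loop(instance, "lcc")


def sim(instance: NildInstance) -> InterventionPlan:
    """Surrounding-impact minimization: pair the top target with the farthest
    safe target (ties: larger LCC, then smaller id)."""
    return _greedy_pair_loop(instance, "hops")


class EnumerationCapError(RuntimeError):
    """Raised when the exhaustive search space exceeds the configured cap."""


def _candidate_universe(instance: NildInstance, widen: bool) -> List[Edge]:
    g = instance.graph
    if instance.is_single:
        t = instance.target
        return [
            gc.canonical_edge((t, v))
            for v in sorted(g.nodes)
            if v != t and not g.has_edge(t, v)
        ]
    if widen:
        pairs = {
            gc.canonical_edge((t, v))
            for t in instance.targets
            for v in g.nodes
            if v != t and not g.has_edge(t, v)
        }
        return sorted(pairs)
    return [
        gc.canonical_edge((a, b))
        for a, b in combinations(sorted(instance.targets), 2)
        if not g.has_edge(a, b)
    ]


def enum_optimal(
    instance: NildInstance,
    max_subsets: int = 500_000,
    widen_candidates: bool = False,
) -> InterventionPlan:
    """Exhaustive optimum over all edge sets of size <= k.

    Candidates are the non-edges incident to the single target, or all
    target-internal non-edges for the multi-target problem
    (``widen_candidates=True`` allows one endpoint outside T).  Among
    degradation-safe sets, plans meeting every centrality floor are preferred;
    then smaller objective, fewer edges, lexicographically smaller edge list.
    Refuses (with the count) when the number of subsets exceeds ``max_subsets``.
    """
    universe = _candidate_universe(instance, widen_candidates)
    k = instance.constraints.k
    total = sum(comb(len(universe), i) for i in range(0, min(k, len(universe)) + 1))
    if total > max_subsets:
        raise EnumerationCapError(
            f"{total} candidate edge sets exceed the cap of {max_subsets}"
        )

    cons = instance.constraints
    best_plan: Optional[InterventionPlan] = None
    best_key: Optional[Tuple] = None
    for size in range(0, min(k, len(universe)) + 1):
        for subset in combinations(universe, size):
            g, metrics = gc.apply_edges(
                instance.graph, instance.baseline_metrics, subset
            )
            worst = max(
                metrics[v].lcc - instance.baseline_lccs[v] for v in instance.graph
            )
            if worst > cons.tau:
                continue
            floors_ok = all(g.degree(t) > cons.omega_d for t in instance.targets)
            # Centralities are non-negative: negative floors hold vacuously.
            if floors_ok and cons.omega_b >= 0:
                bet = gc.all_betweenness(g)
                floors_ok = all(bet[t] > cons.omega_b for t in instance.targets)
            if floors_ok and cons.omega_c >= 0:
                clo = gc.all_closeness(g)
                floors_ok = all(clo[t] > cons.omega_c for t in instance.targets)
            obj = max(metrics[t].lcc for t in instance.targets)
            key = (not floors_ok, obj, size, subset)
            if best_key is None or key < best_key:
                plan = InterventionPlan(
                    edges=tuple(subset),
                    post_graph=g,
                    provenance=tuple(
                        {"edge": e, "index": i, "algorithm": "enum"}
                        for i, e in enumerate(subset)
                    ),
                )
                best_plan, best_key = plan, key
    assert best_plan is not None  # size 0 (the empty set) is always tau-safe
    return best_plan
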