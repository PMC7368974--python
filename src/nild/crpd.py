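"""CRPD: candidate re-selection with preserved dependency, for a single target.

The single-target problem adds k edges incident to the target t.  The greedy
baseline keeps a candidate pool C (nodes individually connectable to t without
breaching the cumulative degradation cap tau), repeatedly commits the
minimum-degree candidate, and prunes from C every node whose addition would now
violate tau — pruned nodes accumulate in R.  Two refinements:

* MISS (multi-measurement integration selection): while the target's
  betweenness or closeness still sits below its floor, candidates are ranked by
  a weighted blend w_b*b(u) + w_c*c(u) + w_d*dnorm(u) instead of minimum
  degree, steering the new ties toward central nodes.  The weights are the
  clipped shortfalls of t's centralities against their floors.
* RNR (removed-node re-selection): after the baseline pass, the minimum-degree
  member of R is force-seeded as t's first new neighbor and the baseline is
  rerun; the better of the two plans wins.  On threshold graphs this recovers
  an exact optimum.

All tie-breaking is by ascending node identifier, making runs deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Set, Tuple

import networkx as nx

from . import graph_core as gc
from .graph_core import Node
from .problem import Constraints, InterventionPlan, NildInstance, edge_addition_feasible

logger = logging.getLogger(__name__)

__all__ = ["MissWeights", "miss_weights", "miss_score", "crpd_baseline", "crpd"]


@dataclass(frozen=True)
class MissWeights:
    """Blend weights for candidate scoring; w_d is the remainder 1 - w_b - w_c."""

    w_b: float
    w_c: float

    def __post_init__(self) -> None:
        if self.w_b < 0 or self.w_c < 0 or self.w_b + self.w_c > 1 + 1e-12:
            raise ValueError(f"invalid MISS weights ({self.w_b}, {self.w_c})")

    @property
    def w_d(self) -> float:
        return 1.0 - self.w_b - self.w_c

    @property
    def inactive(self) -> bool:
        """True when both centrality floors are already met (pure degree rule)."""
        return self.w_b == 0.0 and self.w_c == 0.0


def miss_weights(graph: nx.Graph, t: Node, constraints: Constraints) -> MissWeights:
    """Weights from the target's centrality shortfalls.

    raw_b = max(0, omega_b - b(t)) and likewise for closeness; a floor already
    met contributes weight 0.  If the raw shortfalls sum past 1 they are
    rescaled to sum to 1 so the degree weight w_d = 1 - w_b - w_c stays
    non-negative.
    """
    raw_b = max(0.0, constraints.omega_b - gc.betweenness(graph, t))
    raw_c = max(0.0, constraints.omega_c - gc.closeness(graph, t))
    total = raw_b + raw_c
    if total > 1.0:
        raw_b, raw_c = raw_b / total, raw_c / total
    return MissWeights(w_b=raw_b, w_c=raw_c)


def miss_score(
    graph: nx.Graph,
    u: Node,
    weights: MissWeights,
    normalize_degree: bool = True,
) -> float:
    """w_b*b(u) + w_c*c(u) + w_d*degree(u).

    By default the degree term is normalized by (n - 1) so all three terms
    share the [0, 1] scale; ``normalize_degree=False`` uses the raw degree.
    """
    n = graph.number_of_nodes()
    d = graph.degree(u)
    d_term = d / (n - 1) if (normalize_degree and n > 1) else float(d)
    score = weights.w_d * d_term
    if weights.w_b > 0.0:
        score += weights.w_b * gc.betweenness(graph, u)
    if weights.w_c > 0.0:
        score += weights.w_c * gc.closeness(graph, u)
    return score


def _select_candidate(
    graph: nx.Graph,
    candidates: List[Node],
    weights: MissWeights,
    normalize_degree: bool,
) -> Node:
    """Pick the next candidate: min degree under the pure rule, max blended
    score while a floor is unmet (ties: smaller degree, then smaller id)."""
    if weights.inactive:
        return min(candidates, key=lambda u: (graph.degree(u), u))
    scores = {u: miss_score(graph, u, weights, normalize_degree) for u in candidates}
    best_score = max(scores.values())
    tied = [u for u in candidates if scores[u] == best_score]
    return min(tied, key=lambda u: (graph.degree(u), u))


def crpd_baseline(
    instance: NildInstance,
    initial_plan: Optional[InterventionPlan] = None,
    normalize_degree: bool = True,
) -> Tuple[InterventionPlan, Set[Node]]:
    """One greedy pass; returns the plan and the pruned set R.

    Starts from ``initial_plan`` (empty by default; must itself satisfy tau).
    The candidate pool holds every non-neighbor of t whose single addition is
    tau-feasible on top of the current plan; after each committed edge the pool
    is re-screened and newly infeasible members move to R.  Stops at budget k
    or pool exhaustion (short plans are returned with a warning, not an error).
    """
    t = instance.target
    k = instance.constraints.k
    plan = initial_plan if initial_plan is not None else instance.empty_plan()
    _, metrics = gc.apply_edges(instance.graph, instance.baseline_metrics, plan.edges)

    candidates: List[Node] = []
    for i in sorted(instance.graph.nodes):
        if i == t or plan.post_graph.has_edge(t, i):
            continue
        if edge_addition_feasible(instance, plan, metrics, (t, i)):
            candidates.append(i)
    removed: Set[Node] = set()

    while len(plan) < k and candidates:
        weights = miss_weights(plan.post_graph, t, instance.constraints)
        u = _select_candidate(plan.post_graph, candidates, weights, normalize_degree)
        pre_graph = plan.post_graph
        plan = plan.extended(
            (t, u), algorithm="crpd", rule="degree" if weights.inactive else "miss"
        )
        metrics = gc.update_lccs(pre_graph, metrics, gc.canonical_edge((t, u)))
        candidates.remove(u)
        still_ok: List[Node] = []
        for i in candidates:
            if edge_addition_feasible(instance, plan, metrics, (t, i)):
                still_ok.append(i)
            else:
                removed.add(i)
        candidates = still_ok

    if len(plan) < k:
        logger.warning(
            "candidate pool exhausted: plan has %d of %d edges", len(plan), k
        )
    return plan, removed


def _plan_key(instance: NildInstance, plan: InterventionPlan) -> Tuple[float, float, float]:
    """Comparison key for two candidate plans: lower target LCC wins; ties go
    to larger closeness, then larger betweenness of the target."""
    t = instance.target
    return (
        gc.lcc(plan.post_graph, t),
        -gc.closeness(plan.post_graph, t),
        -gc.betweenness(plan.post_graph, t),
    )


def _prefixes(instance: NildInstance, plan: InterventionPlan):
    """Every prefix of a greedy run, shortest first (the budget is a cap, not
    a quota: a shorter plan that leaves the target's LCC lower wins)."""
    p = instance.empty_plan()
    yield p
    for e, rec in zip(plan.edges, plan.provenance):
        p = p.extended(e, **{k: v for k, v in rec.items() if k not in ("edge", "index")})
        yield p


def crpd(instance: NildInstance, normalize_degree: bool = True) -> InterventionPlan:
    """Full CRPD: baseline pass, then the RNR retry seeded with the
    minimum-degree pruned node; the best prefix of either run wins
    (strictly better to replace, so the baseline run is kept on ties)."""
    if not instance.is_single:
        raise ValueError("crpd solves the single-target problem (|T| = 1)")
    plan, removed = crpd_baseline(instance, None, normalize_degree)
    runs = [plan]
    if removed:
        t = instance.target
        r_m = min(removed, key=lambda r: (instance.graph.degree(r), r))
        seed = instance.empty_plan().extended((t, r_m), algorithm="crpd", rule="rnr-seed")
        retry, _ = crpd_baseline(instance, seed, normalize_degree)
        runs.append(retry)
    best: InterventionPlan | None = None
    best_key = None
    for run in runs:
        for prefix in _prefixes(instance, run):
            key = _plan_key(instance, prefix)
            if best is None or key < best_key:
                best, best_key = prefix, key
    return best
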