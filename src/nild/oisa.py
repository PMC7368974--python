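"""OISA: objective-aware intervention edge selection for multiple targets.

Three cooperating ideas drive the search:

* EORE (expected-objective-reaching exploration) sweeps a short schedule of
  targeted LCC levels l_j = j / C(dhat_2k, 2), where dhat_2k is the maximum
  degree among the (up to) 2k targets with the largest baseline LCC.  For a
  node of degree d and clustering c, bringing its LCC down to level l by pure
  edge addition needs at least k_t new incident edges, the smallest k_t with

      c * d * (d - 1) <= l * (d + k_t) * (d + k_t - 1),

  because added edges can only grow the denominator C(d + k_t, 2) while the
  numerator never shrinks.  Summing per-target needs (each edge serves at most
  two targets) gives a global lower bound k_G; levels with k_G > k are skipped,
  and a level is aborted early once some target's remaining need exceeds the
  remaining budget.
* PONF (poor-optionality node first) picks, per iteration, the target m with
  the maximal current LCC — among ties the one with the *smallest* optionality,
  i.e. the fewest safe partners, since its options only shrink as the graph
  densifies — and pairs it with the largest-LCC member of its option set (or,
  while one of m's centrality floors is unmet, the best MISS-scored member).
  A target u_t is an option for t when it sits >= 3 hops away (no LCC can rise
  at all) or exactly 2 hops away with every common neighbor's cumulative LCC
  increment staying within tau.
* ALC (accelerated LCC calculation) maintains clustering incrementally (only
  the endpoints and common neighbors of an added edge are touched) and skips
  nodes in the max-LCC scan whose closed-form k-edge LCC upper bound

      max_{k1+k2=k} (n_v + k2 + k1*d + C(k1,2)) / C(d + k1, 2)

  already sits below the current maximum — such nodes can never become the
  argmax, so pruning is exactness-preserving and ``use_alc=False`` returns the
  identical plan by full recomputation.

Intervention edges are drawn from within the target set (both endpoints in T),
the same universe the baselines search.  Every prefix of every level's run
competes for the final answer, so the returned plan is never worse than doing
nothing; ties prefer fewer edges, then the lexicographically smaller edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil, comb
from typing import Dict, List, Optional, Set, Tuple

from . import graph_core as gc
from .crpd import miss_score, miss_weights
from .graph_core import Edge, Node
from .problem import InterventionPlan, NildInstance, edge_addition_feasible

logger = logging.getLogger(__name__)

__all__ = [
    "EoreState",
    "OptionSet",
    "min_edges_for_lcc",
    "global_edge_lower_bound",
    "target_lcc_levels",
    "lcc_upper_bound",
    "optionality",
    "ponf_select",
    "eore_prune",
    "oisa",
]


@dataclass
class EoreState:
    """Bookkeeping for one targeted-LCC level."""

    level_index: int
    level: float
    d_cap_2k: int
    per_target_needs: Dict[Node, int]
    global_need: int
    incident_counts: Dict[Node, int] = field(default_factory=dict)


@dataclass(frozen=True)
class OptionSet:
    """The safe partners of a target under the degradation cap."""

    owner: Node
    options: Tuple[Node, ...]

    @property
    def optionality(self) -> int:
        return len(self.options)


def min_edges_for_lcc(lcc: float, degree: int, level: float) -> int:
    """Smallest k_t >= 0 with lcc*d*(d-1) <= level*(d+k_t)*(d+k_t-1).

    Solved in closed form (quadratic root for x = d + k_t), then verified and
    adjusted by unit steps so float rounding at the boundary cannot misreport.
    """
    if level <= 0:
        raise ValueError(f"targeted LCC level must be positive, got {level}")
    if not 0.0 <= lcc <= 1.0 or degree < 0:
        raise ValueError(f"invalid lcc={lcc} or degree={degree}")

    lhs = lcc * degree * (degree - 1)

    def ok(k: int) -> bool:
        return lhs <= level * (degree + k) * (degree + k - 1)

    a = lhs / level
    # x^2 - x - a >= 0  =>  x >= (1 + sqrt(1 + 4a)) / 2
    x = (1.0 + (1.0 + 4.0 * a) ** 0.5) / 2.0
    k = max(0, ceil(x - degree))
    while k > 0 and ok(k - 1):
        k -= 1
    while not ok(k):
        k += 1
    return k


def global_edge_lower_bound(instance: NildInstance, level: float) -> int:
    """ceil(0.5 * sum_t max{k_t, omega_d - d(t)}): each edge serves <= 2 targets."""
    cons = instance.constraints
    total = 0
    for t in instance.targets:
        k_t = min_edges_for_lcc(
            instance.baseline_lccs[t], instance.graph.degree(t), level
        )
        total += max(k_t, cons.omega_d - instance.graph.degree(t))
    return ceil(total / 2)


def target_lcc_levels(instance: NildInstance, scope: str = "graph") -> List[float]:
    """The EORE level schedule l_j = j / C(dhat_2k, 2).

    dhat_2k is the maximum degree among the (up to) 2k targets of largest
    baseline LCC (ties by smaller id).  Levels are emitted while l_j stays
    below the maximal baseline LCC over all of G (``scope="graph"``) or over
    the targets only (``scope="targets"``).  A dhat_2k below 2 admits no level
    and yields an empty schedule with a warning.
    """
    if scope not in ("graph", "targets"):
        raise ValueError(f"unknown level scope: {scope!r}")
    k = instance.constraints.k
    top = sorted(
        instance.targets, key=lambda t: (-instance.baseline_lccs[t], t)
    )[: 2 * k]
    d_cap = max((instance.graph.degree(t) for t in top), default=0)
    if d_cap < 2:
        logger.warning(
            "no targeted-LCC level exists: max degree among top-2k targets is %d", d_cap
        )
        return []
    pool = instance.targets if scope == "targets" else instance.graph.nodes
    max_lcc = max(instance.baseline_lccs[v] for v in pool)
    denom = comb(d_cap, 2)
    levels = []
    j = 1
    while j / denom < max_lcc:
        levels.append(j / denom)
        j += 1
    return levels


def lcc_upper_bound(degree: int, triangle_edges: int, budget: int) -> float:
    """Closed-form ceiling on a node's LCC after any <= ``budget`` added edges.

    Enumerates the budget splits k1 (edges touching the node) + k2 (edges among
    its neighbors): the numerator can gain at most k2 + k1*degree + C(k1, 2)
    edges while the denominator grows to C(degree + k1, 2).  The raw maximum is
    returned and may exceed 1; callers prune with min(raw, 1).
    """
    if degree < 0 or budget < 0 or triangle_edges < 0:
        raise ValueError("degree, triangle_edges and budget must be non-negative")
    if degree >= 2 and triangle_edges > comb(degree, 2):
        raise ValueError(f"triangle_edges={triangle_edges} exceeds C({degree},2)")
    best = 0.0
    for k1 in range(budget + 1):
        d_new = degree + k1
        if d_new < 2:
            continue
        k2 = budget - k1
        val = (triangle_edges + k2 + k1 * degree + comb(k1, 2)) / comb(d_new, 2)
        best = max(best, val)
    return best


def _two_hop_safe(
    instance: NildInstance,
    plan: InterventionPlan,
    metrics: Dict[Node, gc.NodeMetrics],
    t: Node,
    u: Node,
) -> bool:
    """Would (t, u) keep every *common neighbor's* cumulative increment <= tau?"""
    g = plan.post_graph
    common = set(g[t]) & set(g[u])
    updated = gc.update_lccs(g, metrics, (t, u))
    tau = instance.constraints.tau
    return all(updated[c].lcc - instance.baseline_lccs[c] <= tau for c in common)


def optionality(
    instance: NildInstance,
    t: Node,
    current: InterventionPlan,
    metrics: Optional[Dict[Node, gc.NodeMetrics]] = None,
) -> OptionSet:
    """Option set of ``t`` on the current (partially intervened) graph.

    A fellow target qualifies at hop distance >= 3 (including disconnected —
    no node's LCC can rise), or at exactly 2 hops when every common neighbor
    stays within the cumulative cap after the hypothetical edge.
    """
    g = current.post_graph
    if metrics is None:
        _, metrics = gc.apply_edges(
            instance.graph, instance.baseline_metrics, current.edges
        )
    near = dict(gc.nx.single_source_shortest_path_length(g, t, cutoff=2))
    options: List[Node] = []
    for u in instance.targets:
        hops = near.get(u)  # None => >= 3 hops or unreachable
        if u == t or hops == 1:
            continue
        if hops == 2 and not _two_hop_safe(instance, current, metrics, t, u):
            continue
        options.append(u)
    return OptionSet(owner=t, options=tuple(sorted(options)))


def _omega_unmet(instance: NildInstance, graph, m: Node) -> bool:
    cons = instance.constraints
    if graph.degree(m) <= cons.omega_d:
        return True
    w = miss_weights(graph, m, cons)
    return not w.inactive


def _order_options(
    instance: NildInstance,
    current: InterventionPlan,
    lccs: Dict[Node, float],
    m: Node,
    options: Tuple[Node, ...],
) -> List[Node]:
    """Candidate order for u: largest current LCC first (ties: smaller id);
    while one of m's floors is unmet, best MISS score first instead."""
    g = current.post_graph
    if _omega_unmet(instance, g, m):
        w = miss_weights(g, m, instance.constraints)
        scored = {u: miss_score(g, u, w) for u in options}
        return sorted(options, key=lambda u: (-scored[u], -lccs[u], u))
    return sorted(options, key=lambda u: (-lccs[u], u))


def ponf_select(
    instance: NildInstance,
    current: InterventionPlan,
    metrics: Optional[Dict[Node, gc.NodeMetrics]] = None,
    skip: Set[Node] = frozenset(),
) -> Optional[Edge]:
    """One PONF pick: (m, u) or ``None`` when the chosen m has no options.

    m is the maximal-LCC target (ties: smallest optionality, then smallest
    id); ``skip`` holds bound-pruned nodes that provably cannot be the argmax.
    """
    if metrics is None:
        _, metrics = gc.apply_edges(
            instance.graph, instance.baseline_metrics, current.edges
        )
    lccs = {t: metrics[t].lcc for t in instance.targets}
    scan = [t for t in instance.targets if t not in skip] or list(instance.targets)
    top = max(lccs[t] for t in scan)
    tied = [t for t in scan if lccs[t] == top]
    if len(tied) == 1:
        m, opts = tied[0], None
    else:
        option_sets = {t: optionality(instance, t, current, metrics) for t in tied}
        m = min(tied, key=lambda t: (option_sets[t].optionality, t))
        opts = option_sets[m]
    if opts is None:
        opts = optionality(instance, m, current, metrics)
    if not opts.options:
        return None
    u = _order_options(instance, current, lccs, m, opts.options)[0]
    return (m, u)


def eore_prune(
    instance: NildInstance, state: EoreState, plan: InterventionPlan
) -> bool:
    """Abort the level when some target's remaining need is out of reach:
    k - |F| + x_t < max{k_t, omega_d - d_G(t)} for some t."""
    k = instance.constraints.k
    cons = instance.constraints
    for t in instance.targets:
        need = max(state.per_target_needs[t], cons.omega_d - instance.graph.degree(t))
        x_t = state.incident_counts.get(t, 0)
        if k - len(plan) + x_t < need:
            return True
    return False


def oisa(
    instance: NildInstance,
    use_alc: bool = True,
    level_scope: str = "graph",
) -> InterventionPlan:
    """Run the full level sweep and return the best plan found.

    ``use_alc=False`` disables both the incremental metric maintenance and the
    bound-based scan pruning (everything is recomputed from scratch); the
    returned plan is identical by construction.
    """
    cons = instance.constraints
    k = cons.k
    levels = target_lcc_levels(instance, scope=level_scope)

    def plan_key(p: InterventionPlan) -> Tuple[float, int, Tuple[Edge, ...]]:
        lccs = gc.all_lccs(p.post_graph)
        return (max(lccs[t] for t in instance.targets), len(p), p.edges)

    best = instance.empty_plan()
    best_key = plan_key(best)

    bounds = {
        t: min(
            lcc_upper_bound(
                instance.graph.degree(t),
                instance.baseline_metrics[t].triangle_edges,
                k,
            ),
            1.0,
        )
        for t in instance.targets
    }

    for j, level in enumerate(levels, start=1):
        needs = {
            t: min_edges_for_lcc(
                instance.baseline_lccs[t], instance.graph.degree(t), level
            )
            for t in instance.targets
        }
        k_g = global_edge_lower_bound(instance, level)
        if k_g > k:
            continue
        state = EoreState(
            level_index=j,
            level=level,
            d_cap_2k=0,
            per_target_needs=needs,
            global_need=k_g,
        )
        plan = instance.empty_plan()
        metrics = dict(instance.baseline_metrics)
        for _ in range(k):
            if eore_prune(instance, state, plan):
                break
            if use_alc:
                cur_max = max(metrics[t].lcc for t in instance.targets)
                skip = {t for t in instance.targets if bounds[t] < cur_max}
                pick = ponf_select(instance, plan, metrics, skip=skip)
            else:
                # Independent route: batch recomputation, no scan pruning.
                metrics = gc.all_metrics(plan.post_graph)
                pick = ponf_select(instance, plan, metrics)
            if pick is None:
                break
            m, u = pick
            # The option set guards common neighbors; the commit-time check
            # also covers the endpoints' own cumulative increments.
            cur_lccs = {t: metrics[t].lcc for t in instance.targets}
            opts = optionality(instance, m, plan, metrics)
            committed = False
            for cand in _order_options(instance, plan, cur_lccs, m, opts.options):
                e = (m, cand)
                if edge_addition_feasible(instance, plan, metrics, e):
                    pre = plan.post_graph
                    plan = plan.extended(
                        e, algorithm="oisa", level=level, level_index=j
                    )
                    metrics = gc.update_lccs(pre, metrics, gc.canonical_edge(e))
                    for end in gc.canonical_edge(e):
                        state.incident_counts[end] = (
                            state.incident_counts.get(end, 0) + 1
                        )
                    committed = True
                    break
            if not committed:
                break
            key = plan_key(plan)
            if key < best_key:
                best, best_key = plan, key
    return best
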