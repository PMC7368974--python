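"""Problem statements, candidate plans, and constraint auditing.

Both intervention problems share one shape: given a social graph G, a budget k
of new edges F, a degradation cap tau and centrality floors (omega_b, omega_c,
omega_d), find F minimizing the (maximal) LCC over the target set T on the
augmented graph Gbar, subject to

  1. LCC_Gbar(v) - LCC_G(v) <= tau             for every node v (cumulative,
     always measured against the original graph, never edge-by-edge),
  2. betweenness_Gbar(t) > omega_b             for every t in T,
  3. closeness_Gbar(t)   > omega_c             for every t in T,
  4. degree_Gbar(t)      > omega_d             for every t in T.

The floors are strict inequalities.  Instances whose floors are unreachable are
not errors: algorithms return their best-effort plan and the accompanying
:class:`FeasibilityReport` carries the failure and its margins.

Audit functions here (:func:`check_tau`, :func:`check_plan`) recompute every
metric from scratch on the augmented graph, independently of the incremental
bookkeeping the algorithms use internally, so they double as an oracle for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from . import graph_core as gc
from .graph_core import Edge, Node

__all__ = [
    "Constraints",
    "NildInstance",
    "InterventionPlan",
    "FeasibilityReport",
    "check_tau",
    "check_plan",
    "objective",
    "edge_addition_feasible",
]


@dataclass(frozen=True)
class Constraints:
    """Budget and thresholds.  Defaults follow common practice for this model
    family: tau = 0.12, omega_b = 0.01, omega_c = 0.1, no degree floor."""

    k: int
    tau: float = 0.12
    omega_b: float = 0.01
    omega_c: float = 0.1
    omega_d: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"budget k must be >= 1, got {self.k}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if self.omega_d < 0:
            raise ValueError(f"omega_d must be a non-negative integer, got {self.omega_d}")


class NildInstance:
    """A problem statement: graph, ordered target set, constraints.

    The baseline LCC of every node is frozen at construction; the cumulative
    degradation constraint is always evaluated against it.
    """

    def __init__(
        self,
        graph: nx.Graph,
        targets: Sequence[Node],
        constraints: Constraints,
        baseline_lccs: Optional[Mapping[Node, float]] = None,
    ) -> None:
        seen = set()
        ordered: List[Node] = []
        for t in targets:
            if t not in graph:
                raise KeyError(f"target not in graph: {t!r}")
            if t not in seen:
                seen.add(t)
                ordered.append(t)
        if not ordered:
            raise ValueError("target set is empty")
        self.graph = graph
        self.targets: Tuple[Node, ...] = tuple(sorted(ordered))
        self.constraints = constraints
        self.baseline_lccs: Dict[Node, float] = (
            dict(baseline_lccs) if baseline_lccs is not None else gc.all_lccs(graph)
        )
        self.baseline_metrics = gc.all_metrics(graph)

    @property
    def is_single(self) -> bool:
        return len(self.targets) == 1

    @property
    def target(self) -> Node:
        if not self.is_single:
            raise ValueError("instance has multiple targets")
        return self.targets[0]

    def empty_plan(self) -> "InterventionPlan":
        return InterventionPlan(edges=(), post_graph=self.graph, provenance=())


@dataclass(frozen=True)
class InterventionPlan:
    """A selected edge set F, the augmented graph, and a per-edge audit trail.

    Plans are immutable values; :meth:`extended` returns a new plan with one
    more edge.  ``provenance`` records, per edge, which algorithm chose it, at
    which iteration, and under which targeted LCC level (if any).
    """

    edges: Tuple[Edge, ...]
    post_graph: nx.Graph
    provenance: Tuple[Dict, ...] = ()

    def extended(self, e: Edge, **prov) -> "InterventionPlan":
        e = gc.canonical_edge(e)
        post = gc.add_edges(self.post_graph, [e])
        record = {"edge": e, "index": len(self.edges), **prov}
        return InterventionPlan(
            edges=self.edges + (e,),
            post_graph=post,
            provenance=self.provenance + (record,),
        )

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class FeasibilityReport:
    """Per-constraint verdicts with margins for an (instance, plan) pair.

    ``per_target[t]`` maps each of ``betweenness``/``closeness``/``degree`` to
    ``(ok, margin)`` where ``margin = value - floor`` (strictly positive iff
    the strict floor is met).  ``worst_increment`` is the maximal cumulative
    LCC increase over all nodes, ``worst_node`` its (smallest-id) argmax.
    """

    tau_ok: bool
    worst_node: Optional[Node]
    worst_increment: float
    per_target: Dict[Node, Dict[str, Tuple[bool, float]]]
    objective: float

    @property
    def centrality_ok(self) -> bool:
        return all(ok for checks in self.per_target.values() for ok, _ in checks.values())

    @property
    def feasible(self) -> bool:
        return self.tau_ok and self.centrality_ok


def check_tau(
    instance: NildInstance, plan: InterventionPlan
) -> Tuple[bool, Optional[Node], float]:
    """Does every node's cumulative LCC increase stay within tau?

    Returns ``(ok, argmax node, max increment)``; the argmax is the smallest
    node id among maximizers, or ``None`` for an empty graph.
    """
    post = gc.all_lccs(plan.post_graph)
    worst_node: Optional[Node] = None
    worst = 0.0
    for v in sorted(post):
        inc = post[v] - instance.baseline_lccs[v]
        if worst_node is None or inc > worst:
            worst_node, worst = v, inc
    return worst <= instance.constraints.tau, worst_node, worst


def objective(instance: NildInstance, plan: InterventionPlan) -> float:
    """max_{t in T} LCC_Gbar(t) — the quantity both problems minimize."""
    return max(gc.lcc(plan.post_graph, t) for t in instance.targets)


def check_plan(instance: NildInstance, plan: InterventionPlan) -> FeasibilityReport:
    """Full audit: tau condition plus the three strict centrality floors."""
    cons = instance.constraints
    tau_ok, worst_node, worst = check_tau(instance, plan)
    bet = gc.all_betweenness(plan.post_graph)
    clo = gc.all_closeness(plan.post_graph)
    per_target: Dict[Node, Dict[str, Tuple[bool, float]]] = {}
    for t in instance.targets:
        d = plan.post_graph.degree(t)
        per_target[t] = {
            "betweenness": (bet[t] > cons.omega_b, bet[t] - cons.omega_b),
            "closeness": (clo[t] > cons.omega_c, clo[t] - cons.omega_c),
            "degree": (d > cons.omega_d, d - cons.omega_d),
        }
    return FeasibilityReport(
        tau_ok=tau_ok,
        worst_node=worst_node,
        worst_increment=worst,
        per_target=per_target,
        objective=objective(instance, plan),
    )


def edge_addition_feasible(
    instance: NildInstance,
    plan: InterventionPlan,
    metrics: Mapping[Node, gc.NodeMetrics],
    e: Edge,
) -> bool:
    """Would adding ``e`` on top of ``plan`` keep every node within tau?

    Fast path for the greedy loops: only :func:`graph_core.affected_nodes` of
    ``e`` can move, and the caller guarantees (constructively) that the current
    plan is already tau-feasible, so only those nodes need checking.
    ``metrics`` must describe ``plan.post_graph``.
    """
    updated = gc.update_lccs(plan.post_graph, metrics, e)
    tau = instance.constraints.tau
    for v in gc.affected_nodes(plan.post_graph, e):
        if updated[v].lcc - instance.baseline_lccs[v] > tau:
            return False
    return True
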