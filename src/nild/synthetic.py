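"""Seeded generators for graphs and full problem instances.

Threshold graphs — graphs realizable as f(i) + f(j) > t_G for node weights f
and a global threshold t_G — are first-class here because the single-target
algorithm is exactly optimal on them; the generator stores the realizing
weights so tests can verify the defining biconditional directly.  Random
fixtures (Erdős–Rényi, preferential attachment, relaxed caveman) emulate the
high-clustering populations interventions are aimed at.

Instance recipes reproduce the standard experimental setup for this problem
family: the single-target recipe picks a node with LCC above 0.8 (falling back
to the maximal-LCC node when none exists), and the multi-target recipe samples
20% of the nodes from the top-40% LCC stratum.  Everything is reproducible
from (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np

from . import graph_core as gc
from .graph_core import Node
from .problem import Constraints, NildInstance

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdGraphSpec",
    "make_threshold_graph",
    "is_threshold_graph",
    "make_instance",
    "make_planted_multi_instance",
]

_MAX_ATTEMPTS = 30


@dataclass(frozen=True)
class ThresholdGraphSpec:
    """The realizing weights and threshold of a generated threshold graph."""

    weights: Dict[Node, float]
    threshold: float
    seed: int


def make_threshold_graph(n: int, seed: int) -> Tuple[nx.Graph, ThresholdGraphSpec]:
    """Draw node weights uniformly, set t_G at a random quantile of the
    pairwise weight sums, and realize every edge with f(i) + f(j) > t_G."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    weights = {i: float(w) for i, w in enumerate(rng.uniform(0.0, 1.0, size=n))}
    if n >= 2:
        sums = [weights[i] + weights[j] for i, j in combinations(range(n), 2)]
        t_g = float(np.quantile(sums, rng.uniform(0.15, 0.85)))
    else:
        t_g = 1.0
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        if weights[i] + weights[j] > t_g:
            g.add_edge(i, j)
    return g, ThresholdGraphSpec(weights=weights, threshold=t_g, seed=seed)


def is_threshold_graph(graph: nx.Graph, spec: ThresholdGraphSpec) -> bool:
    """Check the defining biconditional for every node pair against ``spec``."""
    for v in graph.nodes:
        if v not in spec.weights:
            raise KeyError(f"spec has no weight for node {v!r}")
    for i, j in combinations(sorted(graph.nodes), 2):
        above = spec.weights[i] + spec.weights[j] > spec.threshold
        if above != graph.has_edge(i, j):
            return False
    return True


def _build_graph(model: str, n: int, seed: int) -> nx.Graph:
    if model == "threshold":
        g, _ = make_threshold_graph(n, seed)
        return g
    if model == "erdos_renyi":
        # Dense enough that small graphs carry triangles and stay connected.
        p = min(1.0, 2.5 * np.log(max(n, 2)) / max(n - 1, 1))
        return nx.gnp_random_graph(n, p, seed=seed)
    if model == "preferential":
        m = max(2, min(3, n - 1))
        return nx.barabasi_albert_graph(n, m, seed=seed)
    raise ValueError(f"unknown graph model: {model!r}")


def _default_constraints(kind: str, graph: nx.Graph) -> Constraints:
    if kind == "single":
        k = max(1, round(0.06 * graph.number_of_nodes()))
    else:
        k = max(1, round(0.06 * max(graph.number_of_edges(), 1)))
    return Constraints(k=k)


def _pick_targets(
    graph: nx.Graph, kind: str, rng: np.random.Generator
) -> Optional[Tuple[Node, ...]]:
    lccs = gc.all_lccs(graph)
    ranked = sorted(graph.nodes, key=lambda v: (-lccs[v], v))
    if max(lccs.values(), default=0.0) <= 0.0:
        return None
    if kind == "single":
        high = [v for v in ranked if lccs[v] > 0.8]
        pool = high if high else ranked[:1]
        return (pool[int(rng.integers(len(pool)))],)
    n = graph.number_of_nodes()
    n_targets = max(2, round(0.2 * n))
    stratum = ranked[: max(n_targets, round(0.4 * n))]
    idx = rng.choice(len(stratum), size=n_targets, replace=False)
    return tuple(sorted(stratum[i] for i in sorted(idx)))


def make_instance(
    kind: str,
    n: int,
    graph_model: str = "erdos_renyi",
    seed: int = 0,
    overrides: Optional[Constraints] = None,
    require_connected: bool = True,
) -> NildInstance:
    """Build a fully seeded problem instance.

    Retries with perturbed sub-seeds (bounded, with a warning) when the drawn
    graph is degenerate: disconnected (if ``require_connected``) or without a
    single clustered node to target.
    """
    if kind not in ("single", "multi"):
        raise ValueError(f"kind must be 'single' or 'multi', got {kind!r}")
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    for attempt in range(_MAX_ATTEMPTS):
        sub_seed = (seed + 7919 * attempt) % (2**31)
        graph = _build_graph(graph_model, n, sub_seed)
        if require_connected and not nx.is_connected(graph):
            continue
        rng = np.random.default_rng(sub_seed + 1)
        targets = _pick_targets(graph, kind, rng)
        if targets is None:
            logger.warning("degenerate graph (no clustering) on attempt %d", attempt)
            continue
        constraints = overrides if overrides is not None else _default_constraints(kind, graph)
        return NildInstance(graph=graph, targets=targets, constraints=constraints)
    raise RuntimeError(
        f"no usable {graph_model} graph with n={n} found in {_MAX_ATTEMPTS} attempts"
    )


def make_planted_multi_instance(
    n_cliques: int = 5,
    clique_size: int = 5,
    rewire_p: float = 0.2,
    seed: int = 0,
    overrides: Optional[Constraints] = None,
) -> NildInstance:
    """Multi-target instance with planted distant high-LCC groups.

    A relaxed caveman graph: ``n_cliques`` cliques of ``clique_size`` nodes
    arranged on a ring, each edge rewired with probability ``rewire_p``.
    Clique members start at (near-)maximal LCC while distinct cliques sit
    several hops apart — the regime where proximity-blind greedy pairing pays
    a degradation penalty.  Targets follow the 20%-of-nodes-from-top-40%-LCC
    recipe; the budget defaults to one edge per clique.
    """
    for attempt in range(_MAX_ATTEMPTS):
        sub_seed = (seed + 104729 * attempt) % (2**31)
        graph = nx.relaxed_caveman_graph(n_cliques, clique_size, rewire_p, seed=sub_seed)
        graph = nx.Graph(graph)  # drop any multi-edge artifacts of rewiring
        graph.remove_edges_from(nx.selfloop_edges(graph))
        if not nx.is_connected(graph):
            continue
        rng = np.random.default_rng(sub_seed + 1)
        targets = _pick_targets(graph, "multi", rng)
        if targets is None:
            continue
        constraints = (
            overrides if overrides is not None else Constraints(k=n_cliques)
        )
        return NildInstance(graph=graph, targets=targets, constraints=constraints)
    raise RuntimeError("no connected planted graph found; relax the parameters")
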