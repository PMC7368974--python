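"""Graph primitives: local clustering, centralities, and incremental updates.

The social network is an undirected simple graph held in a :class:`networkx.Graph`
(no self-loops, no parallel edges, opaque but totally ordered node identifiers).
All algorithms in this package treat graphs as values: operations that add edges
return a new graph and leave their input untouched.

The local clustering coefficient (LCC) of a node ``v`` is

    LCC(v) = n_v / C(d(v), 2),

where ``d(v)`` is the degree and ``n_v`` the number of edges among ``v``'s
neighbors (equivalently, the number of triangles through ``v``).  A node of
degree < 2 has LCC 0 by convention: its neighborhood admits no pairs, and "no
clustering" is the conservative reading that keeps the objective defined for
leaves and isolates.

Betweenness is shortest-path betweenness normalized by C(n-1, 2) (endpoints
excluded), closeness is the Wasserman–Faust variant that scales the classic
reachable-component formula by (r-1)/(n-1); both therefore live in [0, 1] and
fixed thresholds stay scale-free across graph sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf
from typing import Dict, Hashable, Iterable, Mapping, Set, Tuple

import networkx as nx

Node = Hashable
Edge = Tuple[Node, Node]

__all__ = [
    "Node",
    "Edge",
    "NodeMetrics",
    "make_graph",
    "canonical_edge",
    "lcc",
    "all_lccs",
    "triangle_edge_count",
    "betweenness",
    "all_betweenness",
    "closeness",
    "all_closeness",
    "hop_distance",
    "add_edges",
    "affected_nodes",
    "node_metrics",
    "all_metrics",
    "update_lccs",
    "apply_edges",
]


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node structural metrics.

    ``triangle_edges`` is n_v, the number of edges among the node's neighbors.
    ``betweenness``/``closeness`` are optional: the incremental LCC-update path
    maintains only the triangle-based fields (centralities are recomputed
    exactly on demand, never patched incrementally).
    """

    lcc: float
    degree: int
    triangle_edges: int
    betweenness: float | None = None
    closeness: float | None = None

    def __post_init__(self) -> None:
        if self.degree >= 2 and self.triangle_edges > comb(self.degree, 2):
            raise ValueError(
                f"triangle_edges={self.triangle_edges} exceeds "
                f"C({self.degree},2)={comb(self.degree, 2)}"
            )


def make_graph(edges: Iterable[Edge] = (), nodes: Iterable[Node] = ()) -> nx.Graph:
    """Build a validated undirected simple graph from edges and extra nodes."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in edges:
        if a == b:
            raise ValueError(f"self-loop rejected: ({a!r}, {b!r})")
        g.add_edge(a, b)
    return g


def canonical_edge(e: Edge) -> Edge:
    """Order an undirected edge's endpoints ascending for stable bookkeeping."""
    a, b = e
    return (a, b) if not b < a else (b, a)


def _require_node(graph: nx.Graph, v: Node) -> None:
    if v not in graph:
        raise KeyError(f"unknown node: {v!r}")


def triangle_edge_count(graph: nx.Graph, v: Node) -> int:
    """n_v: the number of edges among v's neighbors (= triangles through v)."""
    _require_node(graph, v)
    nbrs = set(graph[v])
    count = 0
    for u in nbrs:
        count += len(nbrs & set(graph[u]))
    return count // 2


def _lcc_value(triangle_edges: int, degree: int) -> float:
    if degree < 2:
        return 0.0
    return triangle_edges / comb(degree, 2)


def lcc(graph: nx.Graph, v: Node) -> float:
    """Local clustering coefficient of ``v``; 0 when ``degree(v) < 2``."""
    return _lcc_value(triangle_edge_count(graph, v), graph.degree(v))


def all_lccs(graph: nx.Graph) -> Dict[Node, float]:
    """LCC for every node, from triangle counts (pointwise equal to :func:`lcc`)."""
    tri = nx.triangles(graph)
    return {v: _lcc_value(tri[v], graph.degree(v)) for v in graph}


def betweenness(graph: nx.Graph, v: Node) -> float:
    _require_node(graph, v)
    return all_betweenness(graph)[v]


def all_betweenness(graph: nx.Graph) -> Dict[Node, float]:
    """Normalized shortest-path betweenness (Brandes), in [0, 1]."""
    return nx.betweenness_centrality(graph, normalized=True)


def closeness(graph: nx.Graph, v: Node) -> float:
    _require_node(graph, v)
    return nx.closeness_centrality(graph, u=v, wf_improved=True)


def all_closeness(graph: nx.Graph) -> Dict[Node, float]:
    return nx.closeness_centrality(graph, wf_improved=True)


def hop_distance(graph: nx.Graph, a: Node, b: Node) -> float:
    """BFS shortest-path length between ``a`` and ``b``; ``inf`` if disconnected."""
    _require_node(graph, a)
    _require_node(graph, b)
    try:
        return nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return inf


def _validate_new_edge(graph: nx.Graph, e: Edge) -> Edge:
    a, b = e
    _require_node(graph, a)
    _require_node(graph, b)
    if a == b:
        raise ValueError(f"self-loop rejected: ({a!r}, {b!r})")
    if graph.has_edge(a, b):
        raise ValueError(f"edge already present: ({a!r}, {b!r})")
    return canonical_edge(e)


def add_edges(graph: nx.Graph, F: Iterable[Edge]) -> nx.Graph:
    """Return a new graph with the edges of ``F`` added (input left unchanged).

    Every pair must span existing, distinct, currently non-adjacent nodes; the
    offending pair is named otherwise.  Pairs are also checked against each
    other, so ``F`` itself cannot contain duplicates.
    """
    out = graph.copy()
    for e in F:
        a, b = _validate_new_edge(out, e)
        out.add_edge(a, b)
    return out


def affected_nodes(graph: nx.Graph, e: Edge) -> Set[Node]:
    """Nodes whose LCC can change when the new edge ``e = (m, u)`` is added.

    Exactly the endpoints plus their common neighbors: for any other node the
    neighborhood and the edges within it are untouched.
    """
    m, u = _validate_new_edge(graph, e)
    return {m, u} | (set(graph[m]) & set(graph[u]))


def node_metrics(graph: nx.Graph, v: Node, with_centrality: bool = False) -> NodeMetrics:
    tri = triangle_edge_count(graph, v)
    d = graph.degree(v)
    return NodeMetrics(
        lcc=_lcc_value(tri, d),
        degree=d,
        triangle_edges=tri,
        betweenness=betweenness(graph, v) if with_centrality else None,
        closeness=closeness(graph, v) if with_centrality else None,
    )


def all_metrics(graph: nx.Graph, with_centrality: bool = False) -> Dict[Node, NodeMetrics]:
    tri = nx.triangles(graph)
    bet = all_betweenness(graph) if with_centrality else {}
    clo = all_closeness(graph) if with_centrality else {}
    return {
        v: NodeMetrics(
            lcc=_lcc_value(tri[v], graph.degree(v)),
            degree=graph.degree(v),
            triangle_edges=tri[v],
            betweenness=bet.get(v),
            closeness=clo.get(v),
        )
        for v in graph
    }


def update_lccs(
    graph: nx.Graph,
    metrics: Mapping[Node, NodeMetrics],
    e: Edge,
) -> Dict[Node, NodeMetrics]:
    """Metrics for ``graph + e``, touching only :func:`affected_nodes`.

    ``graph`` is the *pre-addition* graph and ``metrics`` must be consistent
    with it (spot-checked on the edge's endpoints).  Centrality fields of the
    affected nodes are dropped (set to ``None``) rather than silently left
    stale.  The result is pointwise equal to recomputing :func:`all_lccs` on
    the augmented graph.
    """
    m, u = _validate_new_edge(graph, e)
    for end in (m, u):
        got = metrics[end]
        if got.degree != graph.degree(end):
            raise ValueError(
                f"metrics inconsistent with graph at node {end!r}: "
                f"degree {got.degree} != {graph.degree(end)}"
            )
    common = set(graph[m]) & set(graph[u])
    out = dict(metrics)
    # Endpoints: degree grows by 1; the new neighbor contributes one edge to
    # n_endpoint for each pre-existing common neighbor.
    for end, other in ((m, u), (u, m)):
        old = metrics[end]
        tri = old.triangle_edges + len(common)
        d = old.degree + 1
        out[end] = NodeMetrics(lcc=_lcc_value(tri, d), degree=d, triangle_edges=tri)
    # Common neighbors: neighborhood unchanged, but (m, u) is a new edge in it.
    for c in common:
        old = metrics[c]
        tri = old.triangle_edges + 1
        out[c] = NodeMetrics(
            lcc=_lcc_value(tri, old.degree), degree=old.degree, triangle_edges=tri
        )
    return out


def apply_edges(
    graph: nx.Graph,
    metrics: Mapping[Node, NodeMetrics],
    F: Iterable[Edge],
) -> Tuple[nx.Graph, Dict[Node, NodeMetrics]]:
    """Add edges one at a time, maintaining LCC metrics incrementally.

    Convenience for the algorithm modules: returns the augmented graph and the
    updated metrics without ever recomputing clustering from scratch.
    """
    out = dict(metrics)
    g = graph.copy()
    for e in F:
        out = update_lccs(g, out, e)
        a, b = canonical_edge(e)
        g.add_edge(a, b)
    return g, out
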