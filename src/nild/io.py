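"""File formats: edge lists, GraphML, target files, instance YAML, plan JSON.

Graphs travel as two-column edge lists (whitespace- or comma-delimited, ``#``
comments, string node ids) or GraphML by extension; plans are written as JSON
documents carrying the selected edges, per-edge provenance, the feasibility
report, and enough configuration echo to replay the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Union

import networkx as nx
import yaml

from . import __version__
from . import graph_core as gc
from .problem import Constraints, FeasibilityReport, InterventionPlan, NildInstance

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_targets",
    "load_instance",
    "save_instance",
    "write_plan",
    "read_plan_edges",
]

PathLike = Union[str, Path]


def read_edge_list(path: PathLike) -> nx.Graph:
    """Parse a two-column edge list (or GraphML, by ``.graphml`` extension).

    Blank lines and ``#`` comments are skipped; duplicate edges collapse with
    a warning; self-loops are dropped with a warning; a line without exactly
    two tokens is an error naming the line number.  Node ids are strings.
    """
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        out.add_nodes_from(str(v) for v in g.nodes)
        out.add_edges_from((str(a), str(b)) for a, b in g.edges if a != b)
        return out
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns, got {len(tokens)}: {raw.rstrip()!r}"
                )
            a, b = tokens
            if a == b:
                logger.warning("%s:%d: self-loop (%s) dropped", path, lineno, a)
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                logger.warning("%s:%d: duplicate edge (%s, %s)", path, lineno, a, b)
            g.add_edge(a, b)
    return g


def write_edge_list(graph: nx.Graph, path: PathLike) -> None:
    """Write a tab-separated edge list (isolated nodes are not representable
    in this format and are silently dropped)."""
    path = Path(path)
    with open(path, "w") as fh:
        for a, b in sorted((gc.canonical_edge(e) for e in graph.edges), key=str):
            fh.write(f"{a}\t{b}\n")


def read_targets(path: PathLike) -> List[str]:
    """One target node id per line; '#' comments and blanks ignored."""
    out: List[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def load_instance(path: PathLike) -> NildInstance:
    """Instance YAML: graph path (relative to the YAML file), targets, and
    the scalar constraints k, tau, omega_b, omega_c, omega_d."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    graph_path = Path(doc["graph"])
    if not graph_path.is_absolute():
        graph_path = path.parent / graph_path
    graph = read_edge_list(graph_path)
    constraints = Constraints(
        k=int(doc["k"]),
        tau=float(doc.get("tau", 0.12)),
        omega_b=float(doc.get("omega_b", 0.01)),
        omega_c=float(doc.get("omega_c", 0.1)),
        omega_d=int(doc.get("omega_d", 0)),
    )
    targets = [str(t) for t in doc["targets"]]
    return NildInstance(graph=graph, targets=targets, constraints=constraints)


def save_instance(instance: NildInstance, path: PathLike, graph_path: PathLike) -> None:
    cons = instance.constraints
    doc = {
        "graph": str(graph_path),
        "targets": [str(t) for t in instance.targets],
        "k": cons.k,
        "tau": cons.tau,
        "omega_b": cons.omega_b,
        "omega_c": cons.omega_c,
        "omega_d": cons.omega_d,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _report_to_dict(report: FeasibilityReport) -> Dict:
    return {
        "tau_ok": report.tau_ok,
        "worst_node": None if report.worst_node is None else str(report.worst_node),
        "worst_increment": report.worst_increment,
        "per_target": {
            str(t): {name: {"ok": ok, "margin": margin} for name, (ok, margin) in checks.items()}
            for t, checks in report.per_target.items()
        },
        "centrality_ok": report.centrality_ok,
        "feasible": report.feasible,
        "objective": report.objective,
    }


def write_plan(
    plan: InterventionPlan,
    report: FeasibilityReport,
    path: PathLike,
    config: Dict | None = None,
) -> None:
    """Serialize a plan plus its audit to JSON (lossless for the edge set)."""
    doc = {
        "version": __version__,
        "edges": [[str(a), str(b)] for a, b in plan.edges],
        "provenance": [
            {**{k: v for k, v in rec.items() if k != "edge"},
             "edge": [str(rec["edge"][0]), str(rec["edge"][1])]}
            for rec in plan.provenance
        ],
        "objective": report.objective,
        "report": _report_to_dict(report),
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_plan_edges(path: PathLike) -> List[gc.Edge]:
    with open(path) as fh:
        doc = json.load(fh)
    return [gc.canonical_edge((a, b)) for a, b in doc["edges"]]
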