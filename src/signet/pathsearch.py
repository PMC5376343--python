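"""Shortest and near-shortest source-to-target subnetwork extraction.

A near-shortest path to a target *t* is any source-to-*t* path whose total
distance is at most ``(1 + epsilon)`` times the shortest distance to *t*
(epsilon = 0.2 retains paths up to 20% longer).  The extracted subnetwork
is the union, over all requested targets, of every node and edge lying on
at least one acceptable path; each element is annotated with its
"overflow" — the extra distance, beyond the shortest-path distance, of the
best acceptable path using it.  Shortest-path elements have overflow 0.

The composite subnetwork may itself contain paths longer than acceptable
(combining the detours of two acceptable paths), which is intentional:
membership guarantees participation in at least one acceptable path, not
that every path through the subnetwork is acceptable.

Implementation: a forward Dijkstra pass from the source and one reverse
pass per target give admissible bounds; acceptable simple paths are then
enumerated by a depth-first branch-and-bound search pruned with
``cost_so_far + dbwd_t(v) > (1 + epsilon) * dfwd(t)``.  Enumerating simple
paths (rather than testing the edge inequality
``dfwd(u) + d(u,v) + dbwd_t(v) <= budget`` directly, which is equivalent
to backtracking from the targets with an allowed extra distance) keeps
membership exact on cyclic graphs, where the inequality can be satisfied
only by walks that revisit nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import inf

import networkx as nx
import pandas as pd

from .weights import DistanceAssignment

__all__ = [
    "PathSubnetwork",
    "dijkstra",
    "shortest_subnetwork",
    "near_shortest_subnetwork",
    "unweighted_subnetwork",
]

#: relative slack absorbing float summation error in the acceptability test
_REL_TOL = 1e-9


@dataclass
class PathSubnetwork:
    """Extracted subnetwork with per-element overflow annotations."""

    graph: nx.DiGraph
    source: str
    targets: set[str]
    epsilon: float
    node_overflow: dict[str, float] = field(default_factory=dict)
    edge_overflow: dict[tuple[str, str], float] = field(default_factory=dict)
    shortest_dist: dict[str, float] = field(default_factory=dict)
    #: per (edge, target) overflow, for the path report
    per_target_edge_overflow: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def report(self) -> pd.DataFrame:
        """Long-form per-edge, per-target overflow table."""
        rows = []
        for (u, v), per_t in sorted(self.per_target_edge_overflow.items()):
            for t, ov in sorted(per_t.items()):
                rows.append(
                    {"source": u, "target": v, "path_target": t,
                     "overflow": ov, "shortest_dist": self.shortest_dist[t]}
                )
        return pd.DataFrame(rows, columns=["source", "target", "path_target", "overflow", "shortest_dist"])


def _edge_weights(net: nx.DiGraph, distances: DistanceAssignment | None) -> dict[tuple[str, str], float]:
    dist = distances.effective() if distances is not None else {}
    weights = {}
    for u, v, data in net.edges(data=True):
        if data.get("is_member_link"):
            continue
        weights[(u, v)] = dist.get((u, v), 1.0)
    return weights


def dijkstra(
    net: nx.DiGraph,
    distances: DistanceAssignment | None,
    origin: str,
    reverse: bool = False,
) -> dict[str, float]:
    """Single-source shortest distances; ``reverse=True`` gives distances *to* origin.

    Unreachable nodes are reported with distance ``inf``.  Member-link
    edges (group bookkeeping) never participate.
    """
    if origin not in net:
        raise ValueError(f"origin node {origin!r} absent from network")
    weights = _edge_weights(net, distances)
    for d in weights.values():
        if d <= 0:
            raise ValueError("all edge distances must be positive")
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for (u, v), d in weights.items():
        g.add_edge(u, v, w=d)
    if reverse:
        g = g.reverse()
    best = nx.single_source_dijkstra_path_length(g, origin, weight="w")
    return {n: best.get(n, inf) for n in net.nodes}


def near_shortest_subnetwork(
    net: nx.DiGraph,
    distances: DistanceAssignment | None,
    source: str,
    targets: set[str],
    epsilon: float = 0.2,
) -> PathSubnetwork:
    """Extract all elements on acceptable (within ``(1+epsilon)x``) paths.

    Per-edge overflow is the minimum, over the targets the edge serves, of
    the best acceptable path length through it minus that target's
    shortest distance; a node's overflow is the minimum over its retained
    incident edges.  With ``epsilon=0`` this is exactly the union of
    shortest paths.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    dfwd = dijkstra(net, distances, source)
    reachable = sorted(t for t in targets if t != source and dfwd[t] < inf)
    if not reachable:
        warnings.warn(f"no requested target reachable from {source!r}")
        return PathSubnetwork(nx.DiGraph(), source, set(targets), epsilon)

    # bound the per-target reverse passes to the source-reachable component
    comp = {n for n, d in dfwd.items() if d < inf}
    sub = net.subgraph(comp)
    weights = _edge_weights(sub, distances)
    succ: dict[str, list[tuple[str, float]]] = {}
    for (u, v), d in weights.items():
        succ.setdefault(u, []).append((v, d))

    edge_over: dict[tuple[str, str], float] = {}
    node_over: dict[str, float] = {}
    per_target: dict[tuple[str, str], dict[str, float]] = {}
    shortest = {t: dfwd[t] for t in reachable}
    for t in reachable:
        dbwd = dijkstra(sub, distances, t, reverse=True)
        budget = (1.0 + epsilon) * shortest[t]
        budget += _REL_TOL * max(1.0, abs(budget))

        # depth-first enumeration of all simple source->t paths within
        # budget, pruned by the admissible reverse-distance bound
        path: list[str] = [source]
        on_path = {source}

        def visit(u: str, cost: float) -> None:
            if u == t:
                ov = max(0.0, cost - shortest[t])
                for n in path:
                    if ov < node_over.get(n, inf):
                        node_over[n] = ov
                for e in zip(path, path[1:]):
                    if ov < edge_over.get(e, inf):
                        edge_over[e] = ov
                    if ov < per_target.setdefault(e, {}).get(t, inf):
                        per_target[e][t] = ov
                return
            for v, d in succ.get(u, ()):
                if v in on_path:
                    continue
                c = cost + d
                if c + dbwd[v] > budget:
                    continue
                path.append(v)
                on_path.add(v)
                visit(v, c)
                path.pop()
                on_path.remove(v)

        visit(source, 0.0)

    out = nx.DiGraph(source_id=source)
    for (u, v), ov in edge_over.items():
        data = net.get_edge_data(u, v, default={})
        out.add_edge(u, v, **data, overflow=ov)
    for n, ov in node_over.items():
        out.add_node(n)
        out.nodes[n].update(net.nodes[n])
        out.nodes[n]["overflow"] = ov

    return PathSubnetwork(
        graph=out, source=source, targets=set(targets), epsilon=epsilon,
        node_overflow=node_over, edge_overflow=edge_over,
        shortest_dist=shortest, per_target_edge_overflow=per_target,
    )


def shortest_subnetwork(
    net: nx.DiGraph,
    distances: DistanceAssignment | None,
    source: str,
    targets: set[str],
) -> PathSubnetwork:
    """Union of all strict shortest paths: near-shortest with epsilon = 0."""
    return near_shortest_subnetwork(net, distances, source, targets, epsilon=0.0)


def unweighted_subnetwork(
    net: nx.DiGraph,
    source: str,
    targets: set[str],
    epsilon: float = 0.0,
) -> PathSubnetwork:
    """Near-shortest extraction on hop counts (every edge distance 1)."""
    return near_shortest_subnetwork(net, None, source, targets, epsilon=epsilon)
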