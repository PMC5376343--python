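"""Random walk with return probability and its stationary distribution.

The walk runs on the source-reachable component of the network.  From a
node *i* with successors, the walker moves to successor *j* with
probability ``p_ij = (1 - p0) * (1/d_ij) / sum_k (1/d_ik)`` — shorter
distances mean higher weight — and returns to the origin node with
probability ``p0`` (the same for all nodes).  A node with no successors
returns to the origin with probability 1.  The return edges make the
finite chain ergodic, so the stationary row vector ``pi`` solving
``pi P = pi`` exists and is unique and strictly positive.

Node scores are the stationary probabilities; a second, equal-weight run
gives the topology-only baseline ``pi0`` used to de-bias them.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse

from .weights import DistanceAssignment

__all__ = ["WalkModel", "WalkScores", "build_walk", "stationary_distribution", "score_nodes", "simulate_walk"]


@dataclass
class WalkModel:
    """Row-stochastic transition matrix over an ordered node set."""

    P: sparse.csr_matrix
    p0: float
    node_order: list[str]
    source: str

    def index_of(self, node: str) -> int:
        return self.node_order.index(node)


@dataclass
class WalkScores:
    """Stationary probabilities of the weighted (pi) and equal-weight (pi0) runs."""

    pi: dict[str, float]
    pi0: dict[str, float]
    node_order: list[str]

    def ratio(self, node: str) -> float:
        return self.pi[node] / self.pi0[node]


def _reachable_subgraph(net: nx.DiGraph, source: str) -> nx.DiGraph:
    if source not in net:
        raise ValueError(f"source node {source!r} absent from network")
    keep = nx.descendants(net, source) | {source}
    sub = net.subgraph(keep).copy()
    drop = [(u, v) for u, v, d in sub.edges(data=True) if d.get("is_member_link")]
    sub.remove_edges_from(drop)
    return sub


def build_walk(
    net: nx.DiGraph,
    distances: DistanceAssignment | None,
    source: str,
    p0: float = 0.15,
    equal_weights: bool = False,
) -> WalkModel:
    """Build the transition matrix on the source-reachable component.

    With ``equal_weights=True`` every distance is taken as 1, giving the
    topology-only chain; otherwise the effective (refined if available,
    else base) distances of *distances* are used.
    """
    if not 0 < p0 < 1:
        raise ValueError(f"return probability p0 must be in (0, 1), got {p0}")
    sub = _reachable_subgraph(net, source)
    order = sorted(sub.nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    dist = distances.effective() if distances is not None else {}

    rows, cols, vals = [], [], []
    s = idx[source]
    for u in order:
        i = idx[u]
        succ = list(sub.successors(u))
        if not succ:
            rows.append(i); cols.append(s); vals.append(1.0)
            continue
        if equal_weights:
            inv = {v: 1.0 for v in succ}
        else:
            inv = {v: 1.0 / dist.get((u, v), 1.0) for v in succ}
        z = sum(inv.values())
        for v in succ:
            rows.append(i); cols.append(idx[v]); vals.append((1.0 - p0) * inv[v] / z)
        rows.append(i); cols.append(s); vals.append(p0)
    P = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    P.sum_duplicates()  # a successor edge into the source merges with the return entry
    return WalkModel(P=P, p0=p0, node_order=order, source=source)


def stationary_distribution(
    model: WalkModel, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Solve ``pi P = pi`` by power iteration; returns pi summing to 1.

    Convergence is declared when the L1 change between successive iterates
    drops below *tol* (the stationarity residual then satisfies the same
    bound); failure to converge raises with the residual reported.
    """
    n = model.P.shape[0]
    x = np.full(n, 1.0 / n)
    PT = model.P.T.tocsr()
    for _ in range(max_iter):
        x_new = PT @ x
        x_new /= x_new.sum()
        if np.abs(x_new - x).sum() <= tol:
            return x_new
        x = x_new
    residual = np.abs(PT @ x - x).sum()
    raise RuntimeError(f"power iteration did not converge in {max_iter} steps (residual {residual:.3e})")


def score_nodes(
    net: nx.DiGraph,
    distances: DistanceAssignment,
    source: str,
    p0: float = 0.15,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> WalkScores:
    """Run the weighted and the equal-weight walk; return both score vectors."""
    model_w = build_walk(net, distances, source, p0=p0, equal_weights=False)
    model_0 = build_walk(net, None, source, p0=p0, equal_weights=True)
    pi = stationary_distribution(model_w, tol=tol, max_iter=max_iter)
    pi0 = stationary_distribution(model_0, tol=tol, max_iter=max_iter)
    order = model_w.node_order
    return WalkScores(
        pi=dict(zip(order, pi.tolist())),
        pi0=dict(zip(order, pi0.tolist())),
        node_order=order,
    )


def simulate_walk(model: WalkModel, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Empirical visit frequencies of a sampled trajectory (cross-validation aid).

    Not used by the scoring pipeline, which computes the distribution
    algebraically; this sampler exists so tests can confirm the two agree.
    """
    n = model.P.shape[0]
    P = model.P.toarray()
    visits = np.zeros(n)
    state = model.index_of(model.source)
    for _ in range(n_steps):
        state = rng.choice(n, p=P[state])
        visits[state] += 1
    return visits / visits.sum()
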