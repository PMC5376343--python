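"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings
from math import inf

import networkx as nx
import numpy as np
import pytest

from signet.simulate import FixtureSpec, generate_fixture


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Curation and merge steps warn on purpose; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def bundle():
    """One certified synthetic bundle shared by the integration tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def bundle_files(tmp_path_factory):
    """The same kind of bundle, written to disk for the format round-trips."""
    outdir = tmp_path_factory.mktemp("fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_fixture(FixtureSpec(seed=12), outdir)


def random_weighted_digraph(seed: int, n_max: int = 10, p: float = 0.3) -> tuple[nx.DiGraph, int]:
    """A random directed graph with integer edge distances in [1, 10]."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p:
                g.add_edge(u, v, w=float(rng.integers(1, 11)))
    return g, n


def enumerate_subnetwork_oracle(g: nx.DiGraph, source, targets, eps):
    """Independent oracle: exhaustive simple-path enumeration.

    Returns (node overflows, edge overflows, per-target shortest) computed
    from every simple path within the (1+eps) budget.
    """
    node_over, edge_over, shortest = {}, {}, {}
    for t in targets:
        if t == source or t not in g or not nx.has_path(g, source, t):
            continue
        paths = []
        for p in nx.all_simple_paths(g, source, t):
            length = sum(g.edges[u, v]["w"] for u, v in zip(p, p[1:]))
            paths.append((length, p))
        short = min(length for length, _ in paths)
        shortest[t] = short
        for length, p in paths:
            if length <= (1 + eps) * short + 1e-9:
                ov = length - short
                for n in p:
                    node_over[n] = min(node_over.get(n, inf), ov)
                for e in zip(p, p[1:]):
                    edge_over[e] = min(edge_over.get(e, inf), ov)
    return node_over, edge_over, shortest


class GraphDistances:
    """Adapter exposing a graph's ``w`` attribute as a distance assignment."""

    def __init__(self, g: nx.DiGraph):
        self._g = g

    def effective(self):
        return {(u, v): d["w"] for u, v, d in self._g.edges(data=True)}
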