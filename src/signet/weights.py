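"""Evidence-based edge distances and their random-walk refinement.

Distances encode how plausible an interaction is as a signal-propagation
step, given the node annotations.  Writing ``S_id`` for "source carries
dataset evidence", ``S_mod`` for "source is a phospho-tyrosine modifier",
``T_id`` for "target carries dataset evidence" and ``T_dp`` for "target is
differentially phosphorylated (site-level evidence)", the scheme is:

====  =========================================================
 d    condition (first matching rule wins)
====  =========================================================
 1    S_id and S_mod and T_id
 2    S_mod and T_id
 8    T_dp and not S_mod and not S_id
 6    T_dp and not S_mod and S_id
 3    S_id
 5    otherwise ("normal" edge)
====  =========================================================

The promotion rules (modifier source) precede the demotion rules because a
differentially phosphorylated target is only demoted when the edge does
*not* come from a tyrosine kinase or phosphatase.  After a random-walk
scoring pass, distances are refined as ``d~_ij = d_ij * pi0_i / pi_i``:
edges out of nodes visited more than topology alone predicts are promoted,
under-visited ones demoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import pandas as pd

from .curation import DIRECT_SUBSTRATE, SITE_LEVEL

__all__ = ["DistanceAssignment", "DEFAULT_SCHEME", "assign_distance", "assign_distances", "refine_distances"]

#: the six distance levels, editable through configuration
DEFAULT_SCHEME = {
    "promoted_both": 1.0,
    "modifier_to_identified": 2.0,
    "demoted_plain": 8.0,
    "demoted_identified": 6.0,
    "identified_source": 3.0,
    "normal": 5.0,
}

#: evidence tags that count as "differentially phosphorylated"
DIFF_PHOSPHO_TAGS = frozenset({SITE_LEVEL, DIRECT_SUBSTRATE})


@dataclass
class DistanceAssignment:
    """Per-edge base distances and, after a walk pass, refined ones."""

    base: dict[tuple[str, str], float] = field(default_factory=dict)
    refined: dict[tuple[str, str], float] | None = None
    scheme: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCHEME))

    def effective(self) -> dict[tuple[str, str], float]:
        return self.refined if self.refined is not None else self.base

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "base_d": d,
                "refined_d": (self.refined or {}).get((u, v)),
            }
            for (u, v), d in sorted(self.base.items())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "base_d", "refined_d"])


def assign_distance(
    source_attrs: Mapping,
    target_attrs: Mapping,
    scheme: Mapping[str, float] = DEFAULT_SCHEME,
    diff_phospho_tags: frozenset[str] = DIFF_PHOSPHO_TAGS,
) -> float:
    """Distance for one edge from its endpoint annotations.

    Exactly one rule of the scheme fires; see the module docstring for the
    rule table and its precedence.
    """
    s_id = bool(source_attrs.get("evidence"))
    s_mod = bool(source_attrs.get("is_ptyr_modifier"))
    t_id = bool(target_attrs.get("evidence"))
    t_dp = bool(diff_phospho_tags.intersection(target_attrs.get("evidence") or ()))

    if s_id and s_mod and t_id:
        return float(scheme["promoted_both"])
    if s_mod and t_id:
        return float(scheme["modifier_to_identified"])
    if t_dp and not s_mod and not s_id:
        return float(scheme["demoted_plain"])
    if t_dp and not s_mod and s_id:
        return float(scheme["demoted_identified"])
    if s_id:
        return float(scheme["identified_source"])
    return float(scheme["normal"])


def assign_distances(
    net: nx.DiGraph,
    scheme: Mapping[str, float] = DEFAULT_SCHEME,
    diff_phospho_tags: frozenset[str] = DIFF_PHOSPHO_TAGS,
) -> DistanceAssignment:
    """Apply the scheme to every non-member-link edge of the network."""
    assignment = DistanceAssignment(scheme=dict(scheme))
    for u, v, data in net.edges(data=True):
        if data.get("is_member_link"):
            continue
        assignment.base[(u, v)] = assign_distance(
            net.nodes[u], net.nodes[v], scheme, diff_phospho_tags
        )
    return assignment


def refine_distances(
    base: DistanceAssignment,
    pi: Mapping[str, float],
    pi0: Mapping[str, float],
) -> DistanceAssignment:
    """Refine distances with stationary scores: ``d~_ij = d_ij * pi0_i / pi_i``.

    *pi* is the stationary distribution of the distance-weighted walk and
    *pi0* the topology-only (equal-weight) baseline, both over the
    source-reachable component.  Edges whose source node has no score
    (outside the component, pi undefined or 0) get the base distance scaled
    by the largest pi0/pi ratio observed, i.e. maximally demoted but
    finite, so the graph stays searchable.  A node with pi > 0 but
    pi0 == 0 indicates inconsistent walk runs and is an error.
    """
    ratios: dict[str, float] = {}
    for node, p in pi.items():
        p0 = pi0.get(node, 0.0)
        if p > 0 and p0 == 0:
            raise ValueError(f"node {node} has pi>0 but pi0==0: inconsistent walk runs")
        if p > 0:
            ratios[node] = p0 / p
    if not ratios:
        raise ValueError("no node with positive stationary score")
    worst = max(ratios.values())

    refined = {
        (u, v): d * ratios.get(u, worst) for (u, v), d in base.base.items()
    }
    return DistanceAssignment(base=dict(base.base), refined=refined, scheme=dict(base.scheme))
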