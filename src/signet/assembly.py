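"""Merge selected pathways into one annotated directed interaction network.

The merged network is a :class:`networkx.DiGraph` with one node per
canonical protein id and one edge per ordered pair.  Nodes and edges keep
the list of pathways they come from; interaction types are unioned and
signs combined on a small lattice (conflicting signs become ``unclear``).
Pathway group constructs (sets of interchangeable proteins) are kept as
marked group nodes with bidirectional member links, and "exploded" to
protein-level edges before any path search.

Node attributes: ``pathways`` (list), ``categories`` (list of process
labels from GO term groups), ``is_ptyr_modifier`` (tyrosine kinase or
phosphatase), ``evidence`` (dataset tags), ``is_group`` / ``group_members``,
``unknown_id``.  Edge attributes: ``types`` (list), ``sign``, ``pathways``,
``is_member_link``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable

import networkx as nx
import pandas as pd

from .curation import TargetSet
from .enrichment import Pathway
from .idmap import IdMap, canonicalize

__all__ = [
    "merge_pathways",
    "combine_signs",
    "annotate_categories",
    "annotate_modifiers",
    "annotate_evidence",
    "explode_groups",
    "reachable_targets",
    "target_interaction_census",
    "term_closure",
]

POSITIVE, NEGATIVE, UNCLEAR, UNKNOWN = "positive", "negative", "unclear", "unknown"
_SIGNS = {POSITIVE, NEGATIVE, UNCLEAR, UNKNOWN}


def combine_signs(signs: Iterable[str]) -> str:
    """Join interaction signs: agreement is kept, conflict becomes unclear.

    ``unknown`` is the neutral element; once both a positive and a negative
    report exist the combined sign is ``unclear``.  The join is commutative
    and associative, so merge order never matters.
    """
    out = UNKNOWN
    for s in signs:
        if s not in _SIGNS:
            raise ValueError(f"invalid sign {s!r}")
        if s == UNKNOWN:
            continue
        if out == UNKNOWN:
            out = s
        elif out != s:
            out = UNCLEAR
    return out


def _merge_edge(net: nx.DiGraph, u: str, v: str, types: set[str], sign: str, pathway_id: str) -> None:
    if net.has_edge(u, v):
        data = net.edges[u, v]
        data["types"] = sorted(set(data["types"]) | types)
        data["sign"] = combine_signs([data["sign"], sign])
        if pathway_id not in data["pathways"]:
            data["pathways"].append(pathway_id)
    else:
        net.add_edge(u, v, types=sorted(types), sign=sign, pathways=[pathway_id], is_member_link=False)


def _ensure_node(net: nx.DiGraph, nid: str, pathway_id: str | None = None, **attrs) -> None:
    if nid not in net:
        net.add_node(
            nid, pathways=[], categories=[], is_ptyr_modifier=False,
            evidence=[], is_group=False, group_members=[], unknown_id=False,
        )
    if pathway_id is not None and pathway_id not in net.nodes[nid]["pathways"]:
        net.nodes[nid]["pathways"].append(pathway_id)
    for k, val in attrs.items():
        net.nodes[nid][k] = val


def merge_pathways(pathways: list[Pathway], idmap: IdMap | None = None, source_id: str | None = None) -> nx.DiGraph:
    """Merge pathways into one annotated network, deduplicating nodes/edges.

    Member and interaction ids are canonicalized through *idmap* when given;
    an id the map does not know is kept raw and flagged ``unknown_id`` so
    coverage losses stay visible.  Group constructs become group nodes with
    bidirectional member links (edge attribute ``is_member_link``).
    """
    net = nx.DiGraph(source_id=source_id)

    def _resolve_id(raw: str) -> tuple[str, bool]:
        if idmap is None:
            return raw, True
        for ns in ("uniprot", "KEGG", "HGNC"):
            cid, known = canonicalize(raw, idmap, ns)
            if known:
                return cid, True
        return canonicalize(raw, idmap)[0], False

    def canon(raw: str) -> str:
        return _resolve_id(raw)[0]

    def is_known(raw: str) -> bool:
        return _resolve_id(raw)[1]

    for pw in pathways:
        # resolve pathway-local group ids to global group nodes keyed by
        # their (canonical) member set, so identical groups from different
        # pathways collapse onto one node; members may be nested group ids
        local: dict[str, str] = {}

        def resolve(raw: str, _stack: frozenset = frozenset()) -> str:
            if raw in local:
                return local[raw]
            if raw in pw.groups:
                if raw in _stack:
                    raise ValueError(f"cyclic group nesting at {raw!r} in pathway {pw.id}")
                cmembers = sorted({resolve(m, _stack | {raw}) for m in pw.groups[raw]})
                local[raw] = "GRP:" + "_".join(cmembers)
                return local[raw]
            return canon(raw)

        for raw in sorted(pw.members):
            cid = canon(raw)
            _ensure_node(net, cid, pw.id)
            if not is_known(raw):
                net.nodes[cid]["unknown_id"] = True
                warnings.warn(f"unmappable id {raw!r} in pathway {pw.id}: kept raw")
        for gid in sorted(pw.groups):
            gnode = resolve(gid)
            cmembers = sorted({resolve(m) for m in pw.groups[gid]})
            _ensure_node(net, gnode, pw.id, is_group=True, group_members=cmembers)
            for m in cmembers:
                _ensure_node(net, m, pw.id)
                for a, b in ((gnode, m), (m, gnode)):
                    if not net.has_edge(a, b):
                        net.add_edge(a, b, types=["other"], sign=UNKNOWN,
                                     pathways=[pw.id], is_member_link=True)
                    elif pw.id not in net.edges[a, b]["pathways"]:
                        net.edges[a, b]["pathways"].append(pw.id)
        for src, tgt, types, sign in pw.interactions:
            u, v = resolve(src), resolve(tgt)
            _ensure_node(net, u, pw.id)
            _ensure_node(net, v, pw.id)
            tset = {types} if isinstance(types, str) else set(types)
            _merge_edge(net, u, v, tset, sign, pw.id)
    return net


def term_closure(obo: nx.MultiDiGraph, terms: Iterable[str], relations: set[str] = frozenset({"is_a"})) -> set[str]:
    """Each term together with all its descendants via the given relations.

    The ontology graph follows the obonet convention (edges run child ->
    parent, keyed by relation), so descendants are found by walking
    in-edges backwards from each seed term.
    """
    closure: set[str] = set()
    for term in terms:
        if term not in obo:
            warnings.warn(f"GO id {term} absent from ontology")
            continue
        stack, seen = [term], {term}
        while stack:
            cur = stack.pop()
            closure.add(cur)
            for child, _, rel in obo.in_edges(cur, keys=True):
                if rel in relations and child not in seen:
                    seen.add(child)
                    stack.append(child)
    return closure


def _gaf_terms_by_protein(gaf: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for rec in gaf.itertuples(index=False):
        out.setdefault(str(rec.db_object_id), set()).add(str(rec.go_id))
    return out


def annotate_categories(
    net: nx.DiGraph,
    gaf: pd.DataFrame,
    obo: nx.MultiDiGraph,
    term_groups: dict[str, list[str]],
    relations: set[str] = frozenset({"is_a"}),
) -> nx.DiGraph:
    """Tag nodes with process categories from grouped GO terms.

    A node carries a category iff it is annotated (directly or through a
    descendant term) to any GO id of that category's group.  *gaf* needs
    columns ``db_object_id`` and ``go_id`` with ids canonicalized to the
    network's namespace.
    """
    closures = {cat: term_closure(obo, terms, relations) for cat, terms in term_groups.items()}
    terms_by_protein = _gaf_terms_by_protein(gaf)
    for nid in net.nodes:
        terms = terms_by_protein.get(nid, set())
        cats = sorted(cat for cat, cl in closures.items() if terms & cl)
        net.nodes[nid]["categories"] = cats
    return net


def annotate_modifiers(
    net: nx.DiGraph,
    gaf: pd.DataFrame,
    obo: nx.MultiDiGraph,
    modifier_terms: Iterable[str],
    manual_allow: Iterable[str] = (),
    manual_deny: Iterable[str] = (),
    relations: set[str] = frozenset({"is_a"}),
) -> nx.DiGraph:
    """Flag phospho-tyrosine modifiers (tyrosine kinases / phosphatases).

    GO-derived flags (modifier terms plus descendants) are overridden by the
    manually verified allow / deny lists.
    """
    closure = term_closure(obo, modifier_terms, relations)
    terms_by_protein = _gaf_terms_by_protein(gaf)
    allow, deny = set(manual_allow), set(manual_deny)
    for nid in net.nodes:
        flag = bool(terms_by_protein.get(nid, set()) & closure)
        if nid in deny:
            flag = False
        elif nid in allow:
            flag = True
        net.nodes[nid]["is_ptyr_modifier"] = flag
    return net


def annotate_evidence(net: nx.DiGraph, targets: TargetSet) -> nx.DiGraph:
    """Stamp dataset evidence tags from a curated target set onto nodes."""
    for nid in net.nodes:
        ev = targets.members.get(nid)
        net.nodes[nid]["evidence"] = sorted(ev.tags) if ev else []
    return net


def explode_groups(net: nx.DiGraph) -> nx.DiGraph:
    """Replace group nodes by protein-level edges to/from every member.

    Each non-member-link edge incident to a group is expanded to the
    group's members, inheriting type, sign and provenance (merged with any
    pre-existing edge).  Nested groups are expanded to a fixpoint; the
    result contains no group nodes.  An empty group is an error.
    """
    net = net.copy()
    while True:
        groups = [n for n, d in net.nodes(data=True) if d.get("is_group")]
        if not groups:
            return net
        group_set = set(groups)
        # expand innermost groups first: those whose members are all proteins
        leaves = [g for g in groups if not set(net.nodes[g]["group_members"]) & group_set]
        if not leaves:
            raise ValueError(f"cyclic group membership among {sorted(groups)}")
        for g in leaves:
            members = net.nodes[g]["group_members"]
            if not members:
                raise ValueError(f"group node {g} has no members")
            for u, _, data in list(net.in_edges(g, data=True)):
                if data.get("is_member_link") or u == g:
                    continue
                for m in members:
                    if m != u:
                        _merge_edge_attrs(net, u, m, data)
            for _, v, data in list(net.out_edges(g, data=True)):
                if data.get("is_member_link") or v == g:
                    continue
                for m in members:
                    if m != v:
                        _merge_edge_attrs(net, m, v, data)
            # an enclosing group listing this one inherits its members
            for h in group_set - {g}:
                if h not in net:
                    continue
                h_members = net.nodes[h]["group_members"]
                if g in h_members:
                    merged = [m for m in h_members if m != g]
                    merged += [m for m in members if m not in merged and m != h]
                    net.nodes[h]["group_members"] = merged
            net.remove_node(g)


def _merge_edge_attrs(net: nx.DiGraph, u: str, v: str, data: dict) -> None:
    if net.has_edge(u, v) and not net.edges[u, v].get("is_member_link"):
        cur = net.edges[u, v]
        cur["types"] = sorted(set(cur["types"]) | set(data["types"]))
        cur["sign"] = combine_signs([cur["sign"], data["sign"]])
        cur["pathways"] = sorted(set(cur["pathways"]) | set(data["pathways"]))
    else:
        net.add_edge(u, v, types=list(data["types"]), sign=data["sign"],
                     pathways=list(data["pathways"]), is_member_link=False)


def reachable_targets(net: nx.DiGraph, source: str, targets: set[str]) -> set[str]:
    """Targets reachable from *source* along directed paths."""
    if source not in net:
        raise ValueError(f"source node {source!r} absent from network")
    return (nx.descendants(net, source) | {source}) & targets


def target_interaction_census(net: nx.DiGraph, targets_by_dataset: dict[str, set[str]]) -> dict[str, int]:
    """Count edges whose two endpoints are both identified targets.

    Given exactly two dataset memberships, edges are classified as
    ``both-<name>`` (both endpoints exclusive to that dataset),
    ``involving-shared`` (either endpoint in both datasets) or
    ``cross-dataset`` (endpoints exclusive to different datasets).
    """
    names = sorted(targets_by_dataset)
    if len(names) != 2:
        raise ValueError("census needs exactly two datasets")
    a, b = names
    only_a = targets_by_dataset[a] - targets_by_dataset[b]
    only_b = targets_by_dataset[b] - targets_by_dataset[a]
    shared = targets_by_dataset[a] & targets_by_dataset[b]
    all_t = only_a | only_b | shared

    counts = Counter({f"both-{a}": 0, f"both-{b}": 0, "involving-shared": 0, "cross-dataset": 0, "total": 0})
    for u, v, data in net.edges(data=True):
        if data.get("is_member_link") or u not in all_t or v not in all_t:
            continue
        counts["total"] += 1
        if u in shared or v in shared:
            counts["involving-shared"] += 1
        elif u in only_a and v in only_a:
            counts[f"both-{a}"] += 1
        elif u in only_b and v in only_b:
            counts[f"both-{b}"] += 1
        else:
            counts["cross-dataset"] += 1
    return dict(counts)
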