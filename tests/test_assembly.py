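"""Pathway merging, sign lattice, GO annotation, group explosion, census."""

import io
import itertools

import networkx as nx
import obonet
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signet.assembly import (
    annotate_categories,
    annotate_evidence,
    annotate_modifiers,
    combine_signs,
    explode_groups,
    merge_pathways,
    reachable_targets,
    target_interaction_census,
)
from signet.curation import TargetSet
from signet.enrichment import Pathway

OBO_STUB = """format-version: 1.2
ontology: go

[Term]
id: GO:0007155
name: cell adhesion

[Term]
id: GO:0099901
name: child of cell adhesion
is_a: GO:0007155 ! cell adhesion

[Term]
id: GO:0099903
name: grandchild of cell adhesion
is_a: GO:0099901 ! child

[Term]
id: GO:0004713
name: protein tyrosine kinase activity

[Term]
id: GO:0008283
name: cell population proliferation
"""


@pytest.fixture(scope="module")
def obo():
    return obonet.read_obo(io.StringIO(OBO_STUB))


def gaf(*pairs):
    return pd.DataFrame(
        [{"db_object_id": p, "go_id": g, "evidence": "IDA", "aspect": "P"} for p, g in pairs],
        columns=["db_object_id", "go_id", "evidence", "aspect"],
    )


class TestCombineSigns:
    @pytest.mark.parametrize(
        "signs,expected",
        [
            (["positive", "positive"], "positive"),
            (["positive", "negative"], "unclear"),
            (["unknown", "negative"], "negative"),
            (["unknown"], "unknown"),
            (["negative", "negative", "unknown"], "negative"),
            (["unclear", "positive"], "unclear"),
        ],
    )
    def test_sign_lattice_join(self, signs, expected):
        assert combine_signs(signs) == expected

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from(["positive", "negative", "unknown"]), min_size=1, max_size=6))
    def test_order_independent(self, signs):
        base = combine_signs(signs)
        for perm in itertools.islice(itertools.permutations(signs), 24):
            assert combine_signs(perm) == base
        # associativity: folding pairwise gives the same join
        folded = signs[0]
        for s in signs[1:]:
            folded = combine_signs([folded, s])
        assert folded == base


class TestMergePathways:
    def test_duplicate_edge_deduplicated_with_provenance(self):
        p1 = Pathway("P1", "db", {"A", "B"}, [("A", "B", {"regulation"}, "positive")])
        p2 = Pathway("P2", "db", {"A", "B"}, [("A", "B", {"phosphorylation"}, "positive")])
        net = merge_pathways([p1, p2])
        assert net.number_of_edges() == 1
        data = net.edges["A", "B"]
        assert data["pathways"] == ["P1", "P2"]
        assert data["types"] == ["phosphorylation", "regulation"]

    def test_conflicting_signs_become_unclear(self):
        p1 = Pathway("P1", "db", {"A", "B"}, [("A", "B", {"regulation"}, "positive")])
        p2 = Pathway("P2", "db", {"A", "B"}, [("A", "B", {"regulation"}, "negative")])
        net = merge_pathways([p1, p2])
        assert net.edges["A", "B"]["sign"] == "unclear"

    def test_disjoint_pathways_sum_node_counts(self):
        p1 = Pathway("P1", "db", {"A", "B"})
        p2 = Pathway("P2", "db", {"C", "D", "E"})
        assert merge_pathways([p1, p2]).number_of_nodes() == 5

    def test_edge_count_bounded_by_interaction_rows(self):
        rows = [("A", "B", {"other"}, "unknown")] * 3 + [("B", "C", {"other"}, "unknown")]
        net = merge_pathways([Pathway("P1", "db", {"A", "B", "C"}, rows)])
        assert net.number_of_edges() <= len(rows)
        assert all(d["pathways"] for _, _, d in net.edges(data=True))


class TestCategories:
    def _net(self, *nodes):
        net = nx.DiGraph()
        for n in nodes:
            net.add_node(n, categories=[])
        return net

    def test_direct_annotation_gives_category(self, obo):
        net = annotate_categories(
            self._net("A"), gaf(("A", "GO:0007155")), obo, {"adhesion-motility": ["GO:0007155"]}
        )
        assert net.nodes["A"]["categories"] == ["adhesion-motility"]

    def test_descendant_annotation_propagates_to_category(self, obo):
        # grandchild term, two is_a hops away (oracle: BFS over is_a edges)
        net = annotate_categories(
            self._net("A"), gaf(("A", "GO:0099903")), obo, {"adhesion-motility": ["GO:0007155"]}
        )
        assert net.nodes["A"]["categories"] == ["adhesion-motility"]

    def test_unrelated_terms_give_no_category(self, obo):
        net = annotate_categories(
            self._net("A"), gaf(("A", "GO:0008283")), obo, {"adhesion-motility": ["GO:0007155"]}
        )
        assert net.nodes["A"]["categories"] == []

    def test_empty_gaf_leaves_all_categories_empty(self, obo):
        net = annotate_categories(
            self._net("A", "B"), gaf(), obo, {"adhesion-motility": ["GO:0007155"]}
        )
        assert all(net.nodes[n]["categories"] == [] for n in net)

    def test_absent_go_id_warns(self, obo):
        with pytest.warns(UserWarning, match="absent"):
            annotate_categories(self._net("A"), gaf(), obo, {"x": ["GO:9999999"]})


class TestModifiers:
    def _net(self):
        net = nx.DiGraph()
        for n in ("A", "B", "C"):
            net.add_node(n, is_ptyr_modifier=False)
        return net

    def test_tyrosine_kinase_term_flags_modifier(self, obo):
        net = annotate_modifiers(self._net(), gaf(("A", "GO:0004713")), obo, ["GO:0004713"])
        assert net.nodes["A"]["is_ptyr_modifier"]
        assert not net.nodes["B"]["is_ptyr_modifier"]

    def test_manual_deny_overrides_go_term(self, obo):
        net = annotate_modifiers(
            self._net(), gaf(("A", "GO:0004713")), obo, ["GO:0004713"], manual_deny=["A"]
        )
        assert not net.nodes["A"]["is_ptyr_modifier"]

    def test_manual_allow_overrides_missing_annotation(self, obo):
        net = annotate_modifiers(self._net(), gaf(), obo, ["GO:0004713"], manual_allow=["C"])
        assert net.nodes["C"]["is_ptyr_modifier"]


class TestExplodeGroups:
    def _with_group(self, members, in_edges=(), out_edges=()):
        pw = Pathway(
            "P1", "db", set(members) | {u for u, _ in in_edges} | {v for _, v in out_edges},
            groups={"g": list(members)},
        )
        for u, _ in in_edges:
            pw.interactions.append((u, "g", {"regulation"}, "positive"))
        for _, v in out_edges:
            pw.interactions.append(("g", v, {"regulation"}, "positive"))
        return merge_pathways([pw])

    def test_incident_edges_expand_to_all_members(self):
        net = explode_groups(self._with_group(["A", "B"], in_edges=[("X", "g")]))
        assert set(net.edges) == {("X", "A"), ("X", "B")}
        assert not any(d.get("is_group") for _, d in net.nodes(data=True))

    def test_singleton_group_collapses_to_member(self):
        net = explode_groups(self._with_group(["A"], out_edges=[("g", "Y")]))
        assert set(net.edges) == {("A", "Y")}

    def test_nested_groups_expand_to_fixpoint(self):
        pw = Pathway(
            "P1", "db", {"A", "B", "C", "X"},
            groups={"inner": ["A", "B"], "outer": ["inner", "C"]},
            interactions=[("X", "outer", {"regulation"}, "positive")],
        )
        net = explode_groups(merge_pathways([pw]))
        assert set(net.edges) == {("X", "A"), ("X", "B"), ("X", "C")}

    def test_empty_group_is_an_error(self):
        net = nx.DiGraph()
        net.add_node("G", is_group=True, group_members=[])
        with pytest.raises(ValueError, match="no members"):
            explode_groups(net)

    def test_explosion_preserves_protein_level_reachability(self):
        # oracle: expand each real edge through transitive group membership
        pw = Pathway(
            "P1", "db", {"A", "B", "C", "S", "T"},
            groups={"g1": ["A", "B"], "g2": ["B", "C"]},
            interactions=[
                ("S", "g1", {"other"}, "unknown"),
                ("g2", "T", {"other"}, "unknown"),
                ("A", "C", {"other"}, "unknown"),
            ],
        )
        pre = merge_pathways([pw])
        post = explode_groups(pre)

        def expand(nid, direction):
            node = pre.nodes.get(nid, {})
            if not node.get("is_group"):
                return {nid}
            out = set()
            for m in node["group_members"]:
                out |= expand(m, direction)
            return out

        oracle = nx.DiGraph()
        oracle.add_nodes_from(n for n, d in pre.nodes(data=True) if not d.get("is_group"))
        for u, v, d in pre.edges(data=True):
            if d.get("is_member_link"):
                continue
            for uu in expand(u, "src"):
                for vv in expand(v, "tgt"):
                    if uu != vv:
                        oracle.add_edge(uu, vv)
        proteins = sorted(oracle.nodes)
        for s in proteins:
            expected = nx.descendants(oracle, s)
            assert nx.descendants(post, s) == expected


class TestReachabilityAndCensus:
    def test_chain_reaches_target(self):
        net = nx.DiGraph([("S", "A"), ("A", "T")])
        assert reachable_targets(net, "S", {"T"}) == {"T"}

    def test_upstream_target_not_reached(self):
        net = nx.DiGraph([("T", "S")])
        assert reachable_targets(net, "S", {"T"}) == set()

    def test_missing_source_is_an_error(self):
        with pytest.raises(ValueError, match="source"):
            reachable_targets(nx.DiGraph([("A", "B")]), "S", {"B"})

    def test_random_dag_matches_bfs_oracle(self):
        import numpy as np

        rng = np.random.default_rng(7)
        net = nx.DiGraph()
        net.add_nodes_from(range(50))
        for u in range(50):
            for v in range(u + 1, 50):
                if rng.random() < 0.08:
                    net.add_edge(u, v)
        targets = set(range(10, 40))
        expected = {t for t in targets if t in nx.descendants(net, 0) | {0}}
        assert reachable_targets(net, 0, targets) == expected

    def test_census_classifies_edges_by_dataset_origin(self):
        net = nx.DiGraph([("A", "B"), ("A", "C"), ("C", "D"), ("D", "X")])
        counts = target_interaction_census(
            net, {"mcf7": {"A", "B", "D"}, "mda231": {"C", "D"}}
        )
        assert counts["both-mcf7"] == 1        # A->B
        assert counts["cross-dataset"] == 1    # A->C
        assert counts["involving-shared"] == 1 # C->D (D shared)
        assert counts["both-mda231"] == 0
        assert counts["total"] == 3

    def test_census_with_no_target_target_edges_is_all_zero(self):
        net = nx.DiGraph([("X", "Y")])
        counts = target_interaction_census(net, {"a": {"A"}, "b": {"B"}})
        assert counts["total"] == 0


def test_evidence_annotation_stamps_tags():
    net = nx.DiGraph()
    net.add_node("A", evidence=[])
    net.add_node("B", evidence=[])
    ts = TargetSet()
    ts.add("A", "site-level", "up")
    net = annotate_evidence(net, ts)
    assert net.nodes["A"]["evidence"] == ["site-level"]
    assert net.nodes["B"]["evidence"] == []
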