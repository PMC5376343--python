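"""Target curation: ratio filter, exclusivity, peptide mapping, substrates."""

import warnings

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signet.curation import (
    COMPLEX_LEVEL,
    DIRECT_SUBSTRATE,
    SITE_LEVEL,
    TargetSet,
    map_peptides_to_proteins,
    merge_target_sets,
    select_direct_substrates,
    select_exclusive_peptides,
    select_ratio_targets,
)


def ratio_table(*pairs):
    return pd.DataFrame(pairs, columns=["id", "silac_ratio"])


def peptide_table(*rows):
    return pd.DataFrame(
        rows, columns=["sequence", "phosphosite", "oxidation_state", "condition"]
    )


class TestRatioFilter:
    def test_ten_percent_band_keeps_up_and_down(self):
        ts = select_ratio_targets(ratio_table(("A", 1.25), ("B", 1.02), ("C", 0.80)), 0.10)
        assert ts.ids() == {"A", "C"}
        assert ts.members["A"].direction == "up"
        assert ts.members["C"].direction == "down"
        assert ts.members["A"].tags == {COMPLEX_LEVEL}

    @pytest.mark.parametrize("ratio,kept", [(1.10, True), (0.90, True), (1.09, False), (0.91, False)])
    def test_boundary_is_inclusive_despite_float_representation(self, ratio, kept):
        ts = select_ratio_targets(ratio_table(("A", ratio)), 0.10)
        assert (ts.ids() == {"A"}) is kept

    def test_empty_table_gives_empty_set(self):
        assert len(select_ratio_targets(ratio_table(), 0.10)) == 0

    def test_non_positive_ratio_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            ts = select_ratio_targets(ratio_table(("A", -0.5), ("B", 1.5)), 0.10)
        assert ts.ids() == {"B"}

    def test_threshold_zero_returns_every_protein_with_ratio_not_one(self):
        ts = select_ratio_targets(ratio_table(("A", 1.0), ("B", 1.001), ("C", 0.999)), 0.0)
        assert ts.ids() == {"B", "C"}


class TestExclusivePeptides:
    def test_disjoint_conditions_partition_cleanly(self):
        pos, neg, shared = select_exclusive_peptides(
            peptide_table(("p1", "Y10", "none", "pos"), ("p2", "Y20", "none", "neg"))
        )
        assert pos == {("p1", "Y10")} and neg == {("p2", "Y20")} and shared == set()

    def test_oxidation_only_pair_collapses_and_is_excluded(self):
        pos, neg, shared = select_exclusive_peptides(
            peptide_table(("p1", "Y10", "none", "pos"), ("p1", "Y10", "ox", "neg"))
        )
        assert shared == {("p1", "Y10")} and pos == set() and neg == set()

    def test_duplicate_observations_deduplicate(self):
        pos, _, _ = select_exclusive_peptides(
            peptide_table(("p1", "Y10", "none", "pos"), ("p1", "Y10", "none", "pos"))
        )
        assert pos == {("p1", "Y10")}

    def test_malformed_phosphosite_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="malformed"):
            pos, _, _ = select_exclusive_peptides(
                peptide_table(("p1", "X10", "none", "pos"), ("p2", "Y20", "none", "pos"))
            )
        assert pos == {("p2", "Y20")}

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["p1", "p2", "p3", "p4"]),
                st.sampled_from(["Y1", "Y2", "S3"]),
                st.sampled_from(["none", "ox"]),
                st.sampled_from(["pos", "neg"]),
            ),
            max_size=25,
        )
    )
    def test_partition_invariants(self, rows):
        pos, neg, shared = select_exclusive_peptides(peptide_table(*rows))
        assert pos & neg == set()
        assert (pos | neg) & shared == set()
        observed = {(s, site) for s, site, _, _ in rows}
        assert pos | neg | shared == observed


class TestPeptideToProtein:
    def test_ambiguous_peptide_contributes_all_matching_proteins(self):
        ts = map_peptides_to_proteins({("p1", "Y1")}, set(), {("p1", "Y1"): ["A", "B"]})
        assert ts.ids() == {"A", "B"}
        assert all(ev.tags == {SITE_LEVEL} for ev in ts.members.values())

    def test_protein_with_peptides_in_both_conditions_is_mixed(self):
        ts = map_peptides_to_proteins(
            {("p1", "Y1")}, {("p2", "Y2")}, {("p1", "Y1"): ["A"], ("p2", "Y2"): ["A"]}
        )
        assert ts.members["A"].direction == "mixed"

    def test_no_peptides_gives_empty_set(self):
        assert len(map_peptides_to_proteins(set(), set(), {})) == 0

    def test_orphan_peptide_warns_but_does_not_fail(self):
        with pytest.warns(UserWarning, match="orphan"):
            ts = map_peptides_to_proteins({("p1", "Y1")}, set(), {})
        assert len(ts) == 0


class TestDirectSubstrates:
    def test_in_vitro_peptide_retrieved_in_cells_qualifies(self):
        ts = select_direct_substrates({("p1", "Y1"): ["A"]}, {("p1", "Y1")})
        assert ts.ids() == {"A"}
        assert ts.members["A"].tags == {DIRECT_SUBSTRATE}

    def test_peptide_not_retrieved_in_cells_is_excluded(self):
        ts = select_direct_substrates({("p1", "Y1"): ["A"]}, set())
        assert len(ts) == 0

    def test_per_peptide_exclusion_keeps_protein_with_another_match(self):
        # one excluded peptide, one retrieved peptide: the protein survives
        ts = select_direct_substrates(
            {("p2", "Y2"): ["M"], ("p3", "Y3"): ["M"]},
            {("p2", "Y2"), ("p3", "Y3")},
            forced_excludes=[("M", "p2")],
        )
        assert ts.ids() == {"M"}

    def test_protein_level_exclusion_removes_all_matches(self):
        ts = select_direct_substrates(
            {("p2", "Y2"): ["M"], ("p3", "Y3"): ["M"]},
            {("p2", "Y2"), ("p3", "Y3")},
            forced_excludes=[("M", None)],
        )
        assert len(ts) == 0

    def test_forced_inclusion_added_unconditionally(self):
        ts = select_direct_substrates({}, set(), forced_includes=["P23528"])
        assert ts.ids() == {"P23528"}

    def test_exclusion_of_absent_id_warns(self):
        with pytest.warns(UserWarning, match="never occurs"):
            select_direct_substrates({("p1", "Y1"): ["A"]}, set(), forced_excludes=[("Z", None)])


class TestMerge:
    def test_tags_accumulate_on_union(self):
        a, b = TargetSet(), TargetSet()
        a.add("A", COMPLEX_LEVEL, "up")
        b.add("A", SITE_LEVEL, "up")
        merged, report = merge_target_sets([a, b])
        assert merged.members["A"].tags == {COMPLEX_LEVEL, SITE_LEVEL}
        combo = report.set_index("tag_combination")["n_proteins"]
        assert combo[f"{COMPLEX_LEVEL}+{SITE_LEVEL}"] == 1

    def test_disjoint_sets_sum_with_zero_overlap(self):
        a, b = TargetSet(), TargetSet()
        for pid in ("A", "B"):
            a.add(pid, COMPLEX_LEVEL, "up")
        for pid in ("C", "D", "E"):
            b.add(pid, SITE_LEVEL, "down")
        merged, report = merge_target_sets([a, b])
        assert len(merged) == 5
        assert set(report["tag_combination"]) == {COMPLEX_LEVEL, SITE_LEVEL}

    def test_conflicting_directions_become_mixed(self):
        a, b = TargetSet(), TargetSet()
        a.add("A", COMPLEX_LEVEL, "up")
        b.add("A", SITE_LEVEL, "down")
        merged, _ = merge_target_sets([a, b])
        assert merged.members["A"].direction == "mixed"

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.tuples(
                    st.sampled_from(["A", "B", "C", "D"]),
                    st.sampled_from([COMPLEX_LEVEL, SITE_LEVEL, DIRECT_SUBSTRATE]),
                ),
                max_size=6,
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_merge_commutative_and_associative_on_members(self, groups):
        sets = []
        for grp in groups:
            ts = TargetSet()
            for pid, tag in grp:
                ts.add(pid, tag, "up")
            sets.append(ts)

        def signature(ts):
            return {pid: frozenset(ev.tags) for pid, ev in ts.members.items()}

        forward, _ = merge_target_sets(sets)
        backward, _ = merge_target_sets(list(reversed(sets)))
        nested, _ = merge_target_sets([merge_target_sets(sets[:2])[0], *sets[2:]])
        assert signature(forward) == signature(backward) == signature(nested)
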