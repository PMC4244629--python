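"""Logic engine: enumeration, changed-set prediction, pattern mapping."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from arrlogic import logic
from arrlogic.logic import (COMPARISON_LABELS, DELETION_SETS, LogicStructure,
                            assign_clusters, catalogue,
                            cluster_select_group, enumerate_structures,
                            map_pattern_to_structure, predict_changed_set,
                            superset_closure)

TFS = (1, 10, 12)
NONEMPTY = [frozenset(c) for r in (1, 2, 3)
            for c in itertools.combinations(TFS, r)]


def brute_force_monotone_functions():
    """Independent oracle: all 256 truth tables over 3 TF-presence bits,
    filtered to monotone non-constant, reduced to minimal true points."""
    out = []
    points = [frozenset(c) for r in range(4)
              for c in itertools.combinations(TFS, r)]
    for bits in itertools.product([0, 1], repeat=len(points)):
        f = dict(zip(points, bits))
        if len(set(bits)) == 1:
            continue  # constant
        if any(f[a] and not f[b]
               for a in points for b in points if a <= b):
            continue  # not monotone
        minimal = frozenset(p for p in points
                            if f[p] and not any(f[q] for q in points
                                                if q < p))
        out.append(minimal)
    return out


def brute_force_changed_set(terms):
    """Changed deletion sets straight from the function semantics."""
    full = frozenset(TFS)
    return frozenset(s for s in NONEMPTY
                     if not any(t <= (full - s) for t in terms))


class TestEnumeration:
    def test_matches_truth_table_brute_force(self):
        oracle = brute_force_monotone_functions()
        # non-constant monotone with f(empty)=0 excludes the antichain {∅}
        oracle = [a for a in oracle if frozenset() not in a]
        ours = {s.terms for s in enumerate_structures(3)}
        assert len(oracle) == len(ours) == 18
        assert set(oracle) == ours

    def test_single_tf_structures_present(self):
        terms = {s.terms for s in enumerate_structures(3)}
        for tf in TFS:
            assert frozenset({frozenset({tf})}) in terms

    def test_changed_sets_pairwise_distinct(self):
        changed = [predict_changed_set(s) for s in enumerate_structures(3)]
        assert len(set(changed)) == 18

    def test_cluster_numbering_and_labels(self):
        by_cluster = {s.cluster: s.label for s in enumerate_structures(3)}
        assert by_cluster[7] == "1∨12"
        assert by_cluster[10] == "1∧10∧12"
        assert by_cluster[12] == "1∨(10∧12)"
        assert by_cluster[11] == "(1∧10)∨(1∧12)∨(10∧12)"
        assert by_cluster[16] == "1∧(10∨12)"

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            enumerate_structures(0)

    def test_antichain_validation(self):
        with pytest.raises(ValueError):
            LogicStructure(frozenset({frozenset({1}), frozenset({1, 10})}))
        with pytest.raises(ValueError):
            LogicStructure(frozenset())


class TestChangedSets:
    @pytest.mark.parametrize("terms, expected", [
        # either ARR1 or ARR12 suffices → changed only when both deleted
        ({frozenset({1}), frozenset({12})},
         {frozenset({1, 12}), frozenset({1, 10, 12})}),
        # all three required → every deletion changes the gene
        ({frozenset({1, 10, 12})}, set(NONEMPTY)),
        # any of the three suffices → only the triple deletion changes it
        ({frozenset({1}), frozenset({10}), frozenset({12})},
         {frozenset({1, 10, 12})}),
    ])
    def test_hand_examples(self, terms, expected):
        s = LogicStructure(frozenset(terms))
        assert predict_changed_set(s) == frozenset(expected)

    def test_agrees_with_function_semantics(self):
        for s in enumerate_structures(3):
            assert predict_changed_set(s) == brute_force_changed_set(s.terms)

    def test_changed_sets_are_upward_closed(self):
        # if deleting S changes the gene, deleting any superset does too
        for s in enumerate_structures(3):
            changed = predict_changed_set(s)
            for c in changed:
                for sup in NONEMPTY:
                    if c <= sup:
                        assert sup in changed


class TestClosure:
    @given(st.sets(st.sampled_from(NONEMPTY), min_size=1))
    def test_idempotent(self, family):
        once = superset_closure(family)
        assert superset_closure(once) == once

    @given(st.sets(st.sampled_from(NONEMPTY), min_size=1))
    def test_contains_input_and_is_upward_closed(self, family):
        closed = superset_closure(family)
        assert frozenset(family) <= closed
        for s in closed:
            for sup in NONEMPTY:
                if s <= sup:
                    assert sup in closed


class TestPatternMapping:
    def test_or_pair_pattern(self):
        s, d = map_pattern_to_structure("NNNNDND")
        assert (s.label, d) == ("1∨12", "D")

    def test_and_triple_pattern(self):
        s, d = map_pattern_to_structure("UUUUUUU")
        assert (s.label, d) == ("1∧10∧12", "U")

    def test_mixed_directions_unmapped(self):
        assert map_pattern_to_structure("UNNDNND") is None

    def test_closure_vs_strict_on_partial_pattern(self):
        # D in arr1/12 only: closure imputes the triple → 1∨12
        assert map_pattern_to_structure("NNNNDNN", mode="strict") is None
        s, d = map_pattern_to_structure("NNNNDNN", mode="closure")
        assert (s.label, d) == ("1∨12", "D")

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            map_pattern_to_structure("NNNNNNN")

    def test_strict_agrees_with_brute_force_over_all_patterns(self):
        """Oracle equivalence across the whole 3^7 pattern space."""
        predicted = {predict_changed_set(s): s
                     for s in enumerate_structures(3)}
        n_mapped = 0
        for pattern in itertools.product("UDN", repeat=7):
            if all(p == "N" for p in pattern):
                continue
            got = map_pattern_to_structure(pattern, mode="strict")
            symbols = {p for p in pattern if p != "N"}
            observed = frozenset(DELETION_SETS[i]
                                 for i, p in enumerate(pattern) if p != "N")
            if len(symbols) > 1:
                expected = None
            else:
                expected = predicted.get(observed)
            if expected is None:
                assert got is None
            else:
                assert got is not None and got[0].terms == expected.terms
                n_mapped += 1
        assert n_mapped == 18 * 2  # each structure, each direction

    def test_closure_maps_every_uniform_pattern(self):
        """After closure the 18 changed sets biject with the nonempty
        up-sets of the deletion lattice, so every single-direction pattern
        maps somewhere."""
        for pattern in itertools.product("DN", repeat=7):
            if all(p == "N" for p in pattern):
                continue
            assert map_pattern_to_structure(pattern, mode="closure") is not None


class TestClusterAssignment:
    def test_partition_all_n_unmapped_or_one_cluster(self):
        pats = pd.DataFrame(
            {g: list(p) for g, p in {
                "a": "NNNNDND", "b": "NNNNNNN", "c": "UNNDNND",
                "d": "UUUUUUU"}.items()},
            index=list(COMPARISON_LABELS)).T
        table = assign_clusters(pats)
        assert "b" not in table.index          # all-N dropped
        assert table.loc["c", "cluster"] == 0  # inconsistent
        assert table.loc["a", "cluster"] == 7
        assert table.loc["d", "cluster"] == 10

    def test_catalogue_restriction(self):
        # D in arr1 and arr10/12: closure is the changed set of 1∧(10∨12)
        pats = pd.DataFrame({"g": list("DNNNNDN")},
                            index=list(COMPARISON_LABELS)).T
        assert assign_clusters(pats, n_catalogue=15).loc["g", "cluster"] == 0
        assert assign_clusters(pats, n_catalogue=18).loc["g", "cluster"] == 16

    def test_median_selection_rule(self):
        # one direction, cluster c holds c genes → median size 8,
        # selected = the seven clusters larger than 8
        rows = []
        for c in range(1, 16):
            for i in range(c):
                rows.append((f"g{c}_{i}", c, f"lab{c}", "D"))
        table = pd.DataFrame(
            [(r[1], r[2], r[3]) for r in rows],
            index=[r[0] for r in rows],
            columns=["cluster", "label", "direction"])
        out = cluster_select_group(table)
        selected = set(out.loc[out["selected"], "cluster"])
        assert selected == {9, 10, 11, 12, 13, 14, 15}

    def test_group_map(self):
        rows = {f"g{c}": (c, "x", "D") for c in (5, 7, 9, 10, 15, 4)}
        table = pd.DataFrame.from_dict(
            rows, orient="index", columns=["cluster", "label", "direction"])
        out = cluster_select_group(table, percentile=0.0)
        # all clusters of size 1 > 0th percentile of sizes (0 for absent)
        assert (out.loc[["g5", "g7", "g9"], "group"] == "G2").all()
        assert out.loc["g10", "group"] == "G3"
        assert out.loc["g15", "group"] == "G4"
        assert out.loc["g4", "group"] == "none"  # selected but ungrouped

    def test_absent_cluster_never_selected(self):
        table = pd.DataFrame({"cluster": [7], "label": ["1∨12"],
                              "direction": ["D"]}, index=["g"])
        out = cluster_select_group(table)
        assert set(out.loc[out["selected"], "cluster"]) <= {7}


def test_catalogue_lookup_consistency():
    cat = catalogue()
    for s in cat.structures:
        assert cat.by_changed_set[predict_changed_set(s)] is s
        assert cat.by_cluster[s.cluster] is s
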