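"""Insertion-biased parsimony against a brute-force single-gain oracle,
rate arithmetic and ancestral copy counts."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from wolbcomp.phylodyn import (ROOT_BRANCH, ancestral_copy_counts,
                               assign_insertions_to_branches, branch_id,
                               insertion_rate, rate_ratio,
                               rates_for_branch_sets)
from conftest import get_tree


def dollo_oracle_gain_branch(tree, present):
    """Exhaustive oracle: among branches whose clade contains every
    present leaf, the one with the smallest clade (single gain, no loss)."""
    best = None
    candidates = [(frozenset(l.taxon.label for l in tree.leaf_node_iter()),
                   ROOT_BRANCH)]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        candidates.append((clade, branch_id(node)))
    for clade, bid in candidates:
        if set(present) <= clade:
            if best is None or len(clade) < len(best[0]):
                best = (clade, bid)
    return best[1]


def matrix_from(loci: dict, samples):
    return pd.DataFrame({s: {k: v[i] for k, v in loci.items()}
                         for i, s in enumerate(samples)})


class TestAssignment:
    def test_private_locus_on_terminal_branch(self, seven_taxon_tree):
        samples = [f"s{i}" for i in range(1, 8)]
        loci = {"L1": ["present"] + ["absent"] * 6}
        table = assign_insertions_to_branches(
            matrix_from(loci, samples), seven_taxon_tree)
        assert table.counts == {"s1": 1}
        assert table.violations == []

    def test_universal_locus_on_root_stem(self, seven_taxon_tree):
        samples = [f"s{i}" for i in range(1, 8)]
        loci = {"L1": ["present"] * 7}
        table = assign_insertions_to_branches(
            matrix_from(loci, samples), seven_taxon_tree)
        assert table.counts == {ROOT_BRANCH: 1}

    def test_seven_private_loci_sum_to_seven(self, seven_taxon_tree):
        samples = [f"s{i}" for i in range(1, 8)]
        loci = {f"L{i}": ["absent"] * i + ["present"] + ["absent"] * (6 - i)
                for i in range(7)}
        table = assign_insertions_to_branches(
            matrix_from(loci, samples), seven_taxon_tree)
        assert table.total_events == 7

    def test_no_present_leaf_is_error(self, seven_taxon_tree):
        samples = [f"s{i}" for i in range(1, 8)]
        loci = {"L1": ["absent"] * 7}
        with pytest.raises(ValueError, match="no present leaf"):
            assign_insertions_to_branches(matrix_from(loci, samples),
                                          seven_taxon_tree)

    def test_unrooted_tree_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,(D:1,E:1):1);",
                                 schema="newick", rooting="force-unrooted")
        matrix = matrix_from({"L1": ["present"] * 5}, list("ABCDE"))
        with pytest.raises(ValueError, match="rooted"):
            assign_insertions_to_branches(matrix, tree)

    def test_loss_inside_clade_reported_as_violation(self):
        tree = get_tree("(((A:1,B:1):1,C:1):1,D:1);")
        matrix = matrix_from({"L1": ["present", "absent", "present",
                                     "absent"]}, list("ABCD"))
        table = assign_insertions_to_branches(matrix, tree)
        assert ("L1", "B") in table.violations
        assert table.total_events == 1  # still placed at the MRCA stem

    def test_unknown_states_do_not_constrain(self):
        tree = get_tree("(((A:1,B:1):1,C:1):1,D:1);")
        matrix = matrix_from({"L1": ["present", "unknown", "absent",
                                     "absent"]}, list("ABCD"))
        table = assign_insertions_to_branches(matrix, tree)
        assert table.counts == {"A": 1}
        assert table.violations == []

    def test_matches_oracle_on_random_matrices(self):
        """Exhaustive single-gain oracle on all leaf subsets, 6-leaf trees."""
        trees = [get_tree("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);"),
                 get_tree("((((A:1,B:1):1,C:1):1,(D:1,E:1):1):1,F:1);")]
        samples = list("ABCDEF")
        for tree in trees:
            for r in range(1, 7):
                for present in itertools.combinations(samples, r):
                    row = ["present" if s in present else "absent"
                           for s in samples]
                    table = assign_insertions_to_branches(
                        matrix_from({"L": row}, samples), tree)
                    (bid, n), = table.counts.items()
                    assert n == 1
                    assert bid == dollo_oracle_gain_branch(tree, present)

    def test_events_conserved_one_per_locus(self, seven_taxon_tree):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(1, 8)]
        loci = {}
        for i in range(25):
            row = list(rng.choice(["present", "absent"], size=7))
            if "present" not in row:
                row[0] = "present"
            loci[f"L{i}"] = row
        table = assign_insertions_to_branches(
            matrix_from(loci, samples), seven_taxon_tree)
        assert table.total_events == 25


class TestRates:
    def test_zero_events(self):
        assert insertion_rate(0, [0.001]).rate == 0.0

    def test_inverse_arithmetic(self):
        r = insertion_rate(22, [22 / 6_571])
        assert r.rate == pytest.approx(6_571)

    def test_simple_division(self):
        assert insertion_rate(10, [0.001]).rate == pytest.approx(10_000)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            insertion_rate(1, [0.0])

    def test_branch_set_partition(self, seven_taxon_tree):
        samples = [f"s{i}" for i in range(1, 8)]
        loci = {"L1": ["present"] + ["absent"] * 6,
                "L2": ["present"] + ["absent"] * 6}
        table = assign_insertions_to_branches(
            matrix_from(loci, samples), seven_taxon_tree)
        rates = rates_for_branch_sets(table, {"s1_stem": ["s1"]})
        assert rates[0].insertions == 2
        assert rates[0].rate == pytest.approx(2 / 0.01)


class TestRateRatio:
    def test_printed_fold_differences(self):
        assert rate_ratio(123_422, 6_571) == 18.8
        assert rate_ratio(83_333, 6_571) == 12.7

    def test_equal_rates(self):
        assert rate_ratio(5.0, 5.0) == 1.0

    def test_reciprocal_within_rounding(self):
        a, b = 123_422.0, 6_571.0
        assert rate_ratio(a, b) * (1 / (a / b)) == pytest.approx(
            1.0, abs=0.01)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio(1.0, 0.0)


class TestAncestralCounts:
    def test_single_leaf_equals_observed(self):
        tree = get_tree("(A:1,B:1);")
        matrix = matrix_from({"L1": ["present", "absent"],
                              "L2": ["present", "absent"],
                              "L3": ["present", "present"]}, ["A", "B"])
        counts = ancestral_copy_counts(matrix, tree)
        assert counts["A"] == 3 and counts["B"] == 1

    def test_shared_plus_private(self):
        tree = get_tree("((A:1,B:1):1,C:1);")
        loci = {}
        for i in range(4):  # 4 loci shared by the sisters
            loci[f"sh{i}"] = ["present", "present", "absent"]
        for i in range(3):  # 3 private to each sister
            loci[f"pa{i}"] = ["present", "absent", "absent"]
            loci[f"pb{i}"] = ["absent", "present", "absent"]
        loci["out"] = ["absent", "absent", "present"]
        matrix = matrix_from(loci, list("ABC"))
        counts = ancestral_copy_counts(matrix, tree)
        assert counts["A,B"] == 4       # sister ancestor: shared only
        assert counts["A"] == 7 and counts["B"] == 7
        assert counts["C"] == 1

    def test_star_private_loci_empty_ancestor(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        loci = {f"p{s}": ["present" if x == s else "absent"
                          for x in "ABCD"] for s in "ABCD"}
        counts = ancestral_copy_counts(matrix_from(loci, list("ABCD")), tree)
        assert counts[ROOT_BRANCH] == 0
        assert counts["A,B"] == 0
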