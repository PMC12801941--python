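"""Recombination screens: four-gamete oracle fixtures, permutation-test
behaviour, the 2-of-3 consensus rule, RF distances against a bipartition
oracle, and the silhouette topology scan."""

import itertools
import random as _pyrandom

import dendropy
import numpy as np
import pytest

import wolbcomp as w
from wolbcomp.alnstats import MSA
from wolbcomp.recomb import (consensus_recombination_call, max_chi2, nss,
                             phi_statistic, rf_distance, rf_matrix,
                             screen_gene, topology_cluster_scan)
from conftest import get_tree

PERMS = 499  # test-mode override of the 100,000 default


def four_gamete_incompatible_pairs(msa: MSA):
    """Exhaustive oracle: count site pairs with all four binary gametes."""
    ids = sorted(msa.sequences)
    rows = [msa.sequences[i] for i in ids]
    ncol = msa.n_columns
    informative = []
    for i in range(ncol):
        col = [r[i] for r in rows]
        states = {c: col.count(c) for c in set(col) if c in "ACGT"}
        if sum(1 for v in states.values() if v >= 2) >= 2:
            major = max(sorted(states), key=lambda s: states[s])
            informative.append([c == major if c in "ACGT" else None
                                for c in col])
    n_bad = 0
    for a, b in itertools.combinations(informative, 2):
        gametes = {(x, y) for x, y in zip(a, b)
                   if x is not None and y is not None}
        if len(gametes) == 4:
            n_bad += 1
    return len(informative), n_bad


@pytest.fixture(scope="module")
def chimeric_msa(eight_taxon_trees):
    t1, t2 = eight_taxon_trees
    alns, truth = w.simulate_gene_alignments(t1, t2, 1, 1.0, 1000, 1.0,
                                             seed=42)
    return alns["gene0000"]


@pytest.fixture(scope="module")
def clonal_msa(eight_taxon_trees):
    t1, t2 = eight_taxon_trees
    alns, _ = w.simulate_gene_alignments(t1, t2, 1, 0.0, 1000, 1.0, seed=43)
    return alns["gene0000"]


class TestPermutationTests:
    def test_no_informative_sites_is_no_test(self):
        msa = MSA({"a": "AAAA", "b": "AAAA", "c": "AAAA", "d": "AAAA"})
        assert phi_statistic(msa, n_permutations=PERMS) is None
        assert max_chi2(msa, n_permutations=PERMS) is None
        assert nss(msa, n_permutations=PERMS) is None

    def test_chimera_detected_by_all_three(self, chimeric_msa):
        msa = MSA(chimeric_msa)
        n_inf, n_bad = four_gamete_incompatible_pairs(msa)
        assert n_inf > 20 and n_bad > 0  # oracle: real topology conflict
        assert phi_statistic(msa, n_permutations=PERMS, seed=1).p < 0.05
        assert max_chi2(msa, n_permutations=PERMS, seed=1).p < 0.05
        assert nss(msa, n_permutations=PERMS, seed=1).p < 0.05

    def test_clonal_gene_not_flagged(self, clonal_msa):
        msa = MSA(clonal_msa)
        res = screen_gene("g", msa, n_permutations=PERMS, seed=2)
        assert res.consensus_call is False

    def test_p_invariant_to_label_order(self, chimeric_msa):
        msa = MSA(chimeric_msa)
        shuffled = MSA(dict(reversed(list(chimeric_msa.items()))))
        for test in (phi_statistic, max_chi2, nss):
            a = test(msa, n_permutations=PERMS, seed=3)
            b = test(shuffled, n_permutations=PERMS, seed=3)
            assert a.p == b.p and a.statistic == b.statistic

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            MSA({"a": "ACGT", "b": "ACG"})

    def test_shuffled_chimera_loses_signal(self, chimeric_msa,
                                           eight_taxon_trees):
        # destroying site order by a fixed column permutation makes the
        # clustering tests approximately null
        rng = np.random.default_rng(5)
        cols = rng.permutation(len(next(iter(chimeric_msa.values()))))
        shuffled = MSA({k: "".join(v[i] for i in cols)
                        for k, v in chimeric_msa.items()})
        res = nss(shuffled, n_permutations=PERMS, seed=6)
        assert res.p > 0.05


class TestConsensusRule:
    @pytest.mark.parametrize("ps,expected", [
        ((0.01, 0.04, 0.20), True),
        ((0.01, 0.20, 0.30), False),
        ((0.05, 0.05, 0.05), False),       # strict <
        ((0.01, 0.04, None), True),
        ((0.01, None, None), None),        # untestable
        ((None, None, None), None),
    ])
    def test_two_of_three_rule(self, ps, expected):
        assert consensus_recombination_call(ps) is expected


class TestRFDistance:
    @staticmethod
    def bipartitions(newick: str) -> set[frozenset]:
        """Oracle: non-trivial unrooted splits by leaf-set recursion."""
        tree = dendropy.Tree.get(data=newick, schema="newick")
        all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        splits = set()
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(below) < len(all_leaves) - 1:
                splits.add(min(below, all_leaves - below, key=sorted))
        return splits

    def test_identical_topologies(self):
        a = get_tree("((A,B),(C,D));")
        b = get_tree("((B,A),(D,C));")
        assert rf_distance(a, b) == 0

    def test_four_taxon_swap(self):
        a = get_tree("((A,B),(C,D));")
        b = get_tree("((A,C),(B,D));")
        assert rf_distance(a, b) == 2

    def test_matches_bipartition_oracle_on_random_trees(self):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(8)]
        tns = dendropy.TaxonNamespace(taxa)
        trees = [dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
            num_extant_tips=8, rng=_pyrandom.Random(int(rng.integers(1e6))))
            for _ in range(6)]
        for a, b in itertools.combinations(trees, 2):
            na, nb = (t.as_string(schema="newick") for t in (a, b))
            oracle = len(self.bipartitions(na) ^ self.bipartitions(nb))
            assert rf_distance(a, b) == oracle

    def test_metric_axioms_and_bound(self):
        rng = np.random.default_rng(8)
        taxa = [f"t{i}" for i in range(7)]
        tns = dendropy.TaxonNamespace(taxa)
        trees = [dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=tns,
            num_extant_tips=7, rng=_pyrandom.Random(int(rng.integers(1e6))))
            for _ in range(5)]
        n = 7
        for a, b, c in itertools.combinations(trees, 3):
            dab, dba = rf_distance(a, b), rf_distance(b, a)
            assert dab == dba                       # symmetry
            assert rf_distance(a, a) == 0           # identity
            assert dab <= rf_distance(a, c) + rf_distance(c, b)  # triangle
            assert dab <= 2 * (n - 3)               # theoretical bound

    def test_mismatched_leaves_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(get_tree("((A,B),(C,D));"),
                        get_tree("((A,B),(C,E));"))


class TestTopologyScan:
    def test_identical_trees_degenerate(self):
        trees = [get_tree("((A:1,B:1):1,(C:1,D:1):1);") for _ in range(12)]
        scan = topology_cluster_scan(trees)
        assert scan.degenerate and scan.best is None

    def test_planted_two_cluster_structure(self):
        t1 = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        t2 = "(((A:1,E:1):1,(C:1,G:1):1):1,((B:1,F:1):1,(D:1,H:1):1):1);"
        trees = [get_tree(t1) for _ in range(20)] + \
                [get_tree(t2) for _ in range(20)]
        scan = topology_cluster_scan(trees, seed=0)
        method, k, score = scan.best
        assert k == 2
        assert score > 0.9
        # full k range emitted for every method
        assert sorted(scan.silhouette["k"].unique()) == list(range(2, 11))
        assert set(scan.silhouette["method"]) == {"hierarchical", "kmeans",
                                                  "kmedoids"}

    def test_too_few_trees_rejected(self):
        trees = [get_tree("((A:1,B:1):1,(C:1,D:1):1);") for _ in range(5)]
        with pytest.raises(ValueError):
            topology_cluster_scan(trees)
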