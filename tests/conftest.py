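"""Shared fixtures: small synthetic references, trees and read sets."""

import dendropy
import pytest

import wolbcomp as w


def get_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted")


@pytest.fixture(scope="session")
def small_reference():
    """60 kb genome, 10 IS copies, one duplicated 5 kb cassette."""
    spec = w.GenomeSpec(length=60_000, is_copy_count=10,
                        duplicated_region_length=5_000, seed=11)
    return w.simulate_reference(spec)


@pytest.fixture(scope="session")
def small_reads(small_reference):
    """50x error-free pairs of the unedited reference sample."""
    sim = w.ReadSimSpec(depth=50, seed=7)
    return w.simulate_pair_alignments(small_reference, w.SampleSpec(), sim)


@pytest.fixture(scope="session")
def seven_taxon_tree():
    return get_tree(
        "(((s1:0.01,s2:0.01):0.02,(s3:0.015,s4:0.015):0.015):0.02,"
        "((s5:0.02,s6:0.02):0.02,s7:0.04):0.01);")


@pytest.fixture(scope="session")
def eight_taxon_trees():
    """Two discordant 8-taxon topologies on one taxon set."""
    t_main = get_tree(
        "(((A:0.08,B:0.08):0.08,(C:0.08,D:0.08):0.08):0.08,"
        "((E:0.08,F:0.08):0.08,(G:0.08,H:0.08):0.08):0.08);")
    t_alt = get_tree(
        "(((A:0.08,E:0.08):0.08,(C:0.08,G:0.08):0.08):0.08,"
        "((B:0.08,F:0.08):0.08,(D:0.08,H:0.08):0.08):0.08);")
    return t_main, t_alt
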