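"""Insertion-biased (Dollo-style) placement of IS gains on a phylogeny.

Complete excisions of IS elements are rare, so presence/absence
differences between strains are explained by insertions only: each locus
gains exactly once, on the branch above the most recent common ancestor
(MRCA) of the leaves where it is present, and is never lost.  Branch
lengths (substitutions/site) approximate time, giving insertion rates in
insertions per (substitution/site) and fold ratios between named branch
sets.

Input trees must be rooted; ``unknown`` states do not constrain
placement; a locus ``absent`` in a leaf nested inside the present clade
contradicts the no-loss model and is reported as a violation rather than
silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"
ROOT_BRANCH = "__root__"


@dataclass
class BranchEventTable:
    """Per-branch insertion counts and branch lengths.

    Branch ids are the sorted, comma-joined leaf labels below the branch;
    the root stem is ``__root__``.
    """

    counts: dict[str, int]
    lengths: dict[str, float]
    violations: list[tuple[str, str]] = field(default_factory=list)
    # (locus id, offending leaf) pairs breaking the no-loss model

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class InsertionRate:
    label: str
    insertions: int
    total_length: float
    rate: float


def _require_rooted(tree: dendropy.Tree) -> None:
    if not tree.is_rooted:
        raise ValueError("a rooted tree is required")
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError("a rooted tree is required (root has >2 children)")


def branch_id(node: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return ",".join(leaves)


def assign_insertions_to_branches(matrix: pd.DataFrame,
                                  tree: dendropy.Tree) -> BranchEventTable:
    """Place each locus gain on the stem of the present-leaf MRCA.

    ``matrix``: loci x samples over {present, absent, unknown}; samples
    must equal the tree's leaf labels.  A locus present in every leaf is
    assigned to the root stem.  A locus with no present leaf is an error.
    """
    _require_rooted(tree)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    samples = set(matrix.columns)
    if leaves != samples:
        raise ValueError("matrix samples do not match tree leaves")

    counts: dict[str, int] = {}
    lengths: dict[str, float] = {ROOT_BRANCH: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        lengths[branch_id(node)] = float(node.edge.length or 0.0)

    violations: list[tuple[str, str]] = []
    for locus, row in matrix.iterrows():
        present = [s for s in matrix.columns if row[s] == PRESENT]
        if not present:
            raise ValueError(f"locus {locus!r} has no present leaf: "
                             "no gain to place")
        if set(present) == leaves:
            mrca = tree.seed_node
        else:
            mrca = tree.mrca(taxon_labels=present)
        if mrca is tree.seed_node:
            bid = ROOT_BRANCH
            clade = leaves
        else:
            bid = branch_id(mrca)
            clade = {lf.taxon.label for lf in mrca.leaf_iter()}
        counts[bid] = counts.get(bid, 0) + 1
        for s in clade:
            if row[s] == ABSENT:
                violations.append((str(locus), s))
    return BranchEventTable(counts=counts, lengths=lengths,
                            violations=violations)


def insertion_rate(events: int, branch_lengths: Sequence[float],
                   label: str = "") -> InsertionRate:
    """Insertions per unit branch length (substitutions/site)."""
    total = float(sum(branch_lengths))
    if total <= 0:
        raise ValueError("total branch length must be positive")
    return InsertionRate(label, events, total, events / total)


def rate_ratio(rate_a: float, rate_b: float) -> float:
    """Fold difference between two insertion rates, at 1 decimal place."""
    if rate_b <= 0:
        raise ValueError("denominator rate must be positive")
    return round(rate_a / rate_b, 1)


def rates_for_branch_sets(table: BranchEventTable,
                          branch_sets: Mapping[str, Sequence[str]]
                          ) -> list[InsertionRate]:
    """Insertion rates over named, user-supplied branch partitions."""
    out = []
    for label, branches in branch_sets.items():
        events = sum(table.counts.get(b, 0) for b in branches)
        lengths = [table.lengths[b] for b in branches]
        out.append(insertion_rate(events, lengths, label))
    return out


def ancestral_copy_counts(matrix: pd.DataFrame,
                          tree: dendropy.Tree) -> dict[str, int]:
    """Minimum IS copy count at each node under the single-gain model.

    A locus counts at node v iff its gain branch is the stem of v or of
    an ancestor of v, i.e. v lies inside the gained clade.  Leaf counts
    equal observed present counts (unknowns inside a gained clade are
    imputed present).  Keys are branch ids (leaf label for leaves).
    """
    _require_rooted(tree)
    table = assign_insertions_to_branches(matrix, tree)
    counts: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        bid = branch_id(node) if node is not tree.seed_node else ROOT_BRANCH
        n = table.counts.get(ROOT_BRANCH, 0)
        anc = node
        chain = []
        while anc is not None:
            if anc is not tree.seed_node:
                chain.append(branch_id(anc))
            anc = anc.parent_node
        n += sum(table.counts.get(b, 0) for b in chain)
        counts[bid] = n
    return counts


def event_table_tsv(path: str, table: BranchEventTable) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tinsertions\tbranch_length\n")
        for bid in sorted(set(table.lengths) | set(table.counts)):
            fh.write(f"{bid}\t{table.counts.get(bid, 0)}\t"
                     f"{table.lengths.get(bid, 0.0):.6g}\n")
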