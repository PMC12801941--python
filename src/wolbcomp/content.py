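"""Gene-content comparison across genomes.

Orthogroup count tables are binarized (universally single-copy
orthogroups dropped, multi-copy counts collapsed to 1) and genomes are
clustered by average-linkage agglomeration on the binary profiles.
Lineage-level presence uses a completeness-aware rule: a lineage *has*
an orthogroup iff it is present in the lineage's designated complete
genome and in at least one draft genome of the same lineage -- guarding
against both assembly gaps (drafts) and annotation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class GenomeMeta:
    genome: str
    lineage: str
    completeness: str  # "complete" | "draft"

    def __post_init__(self):
        if self.completeness not in ("complete", "draft"):
            raise ValueError(f"unknown completeness {self.completeness!r}")


def binarize_orthogroups(counts: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence matrix from orthogroup counts.

    Orthogroups with count exactly 1 in *every* genome are excluded
    (no content signal); remaining counts map >0 -> 1.
    """
    if counts.empty:
        raise ValueError("empty count table")
    single = (counts == 1).all(axis=1)
    binary = (counts.loc[~single] > 0).astype(int)
    return binary


def cluster_genomes(binary: pd.DataFrame, metric: str = "euclidean"
                    ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram of genomes on binary profiles.

    Orthogroups absent everywhere are dropped first.  Returns the scipy
    linkage matrix and the genome order (columns, sorted for
    column-order invariance).
    """
    if binary.shape[1] < 2:
        raise ValueError("need at least 2 genomes to cluster")
    data = binary.loc[binary.any(axis=1)]
    order = sorted(binary.columns)
    profiles = data[order].T.to_numpy(dtype=float)
    dist = pdist(profiles, metric=metric)
    return linkage(dist, method="average"), order


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


@dataclass(frozen=True)
class LineageSets:
    uniquely_present: dict[str, set[str]]
    uniquely_absent: dict[str, set[str]]


def lineage_has(binary: pd.DataFrame, lineage: str,
                meta: Sequence[GenomeMeta]) -> pd.Series:
    """Boolean per orthogroup: the lineage's complete genome has it AND
    at least one draft genome of the lineage has it."""
    complete = [m.genome for m in meta
                if m.lineage == lineage and m.completeness == "complete"]
    drafts = [m.genome for m in meta
              if m.lineage == lineage and m.completeness == "draft"]
    if len(complete) != 1:
        raise ValueError(
            f"lineage {lineage!r} must have exactly one complete genome")
    has = binary[complete[0]] > 0
    if drafts:
        has = has & (binary[drafts] > 0).any(axis=1)
    return has


def lineage_unique_genes(binary: pd.DataFrame,
                         meta: Sequence[GenomeMeta]) -> LineageSets:
    """Per-lineage uniquely present / uniquely absent orthogroup sets.

    uniquely_present(L): orthogroups L has but no other lineage has;
    uniquely_absent(L): orthogroups every other lineage has but L lacks.
    """
    genomes = set(binary.columns)
    covered = {m.genome for m in meta}
    if not genomes <= covered:
        raise ValueError(f"genomes without lineage metadata: "
                         f"{sorted(genomes - covered)}")
    lineages = sorted({m.lineage for m in meta if m.genome in genomes})
    has = {L: lineage_has(binary, L, meta) for L in lineages}
    present: dict[str, set[str]] = {}
    absent: dict[str, set[str]] = {}
    for L in lineages:
        others = [o for o in lineages if o != L]
        only = has[L]
        everyone_else = pd.Series(True, index=binary.index)
        none_else = pd.Series(True, index=binary.index)
        for o in others:
            everyone_else &= has[o]
            none_else &= ~has[o]
        present[L] = set(binary.index[only & none_else])
        absent[L] = set(binary.index[~only & everyone_else])
    return LineageSets(uniquely_present=present, uniquely_absent=absent)


# --- tabular I/O ---------------------------------------------------------

def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path: str) -> list[GenomeMeta]:
    df = pd.read_csv(path, sep="\t")
    return [GenomeMeta(r["genome"], r["lineage"], r["completeness"])
            for _, r in df.iterrows()]
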