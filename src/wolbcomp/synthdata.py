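"""Synthetic genomes, read-pair alignments and gene alignments with truth.

Emulates the data of a masked-reference resequencing experiment on a small
(~1.3 Mb) circular endosymbiont genome carrying many identical copies of a
~1.5 kb insertion-sequence (IS) element and, optionally, a duplicated
~14 kb cassette:

* :func:`simulate_reference` builds the reference genome, its repeat
  annotation and the IS consensus, and can mask all IS copies plus one
  cassette copy (the masked-reference setup used for coverage-ratio copy
  number and read-pair insertion calling).
* :func:`simulate_pair_alignments` renders error-free paired reads of a
  *sample* genome (the reference plus planted IS insertions/excisions)
  directly as idealized SAM records: each read maps to where its sequence
  actually came from.  No alignment algorithm is run -- the downstream
  evidence rules consume mapper output fields, not mappings.
* :func:`simulate_gene_alignments` evolves gene alignments on one topology
  (non-recombinant) or stitches two topologies (recombinant), the planted
  truth for the recombination screens.

Mapping-by-provenance semantics: reads from an IS copy map to the IS
consensus (all copies are masked in the reference); reads from the masked
cassette copy map to the unmasked copy; reads spanning a provenance
boundary are split, the longest segment becoming the primary record and
the rest supplementary records, so per-base depth is conserved.  TLEN is 0
when mates land on different reference sequences; a reference-annotated IS
absent from the sample inflates |TLEN| by the IS length; the proper-pair
flag requires both mates on one reference with |TLEN| within
insert_mean +/- 4*insert_sd.

All randomness stems from one integer seed, split into independent
streams (genome construction, fragment sampling, gene simulation) with
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import random
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from dendropy.model import discrete as _discrete

from .coverage import Interval
from .samio import AlignmentRecord

GENOME = "genome"
IS_CONSENSUS = "IS_consensus"

_BASES = np.array(list("ACGT"))


# --- specifications ------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the reference genome to simulate.

    ``length`` is the total genome length including planted features.
    Defaults emulate a ~1.37 Mb endosymbiont chromosome with a 1.5 kb IS
    element and an optional 14,133 bp duplicated cassette.
    """

    length: int = 1_365_198
    circular: bool = True
    is_element_length: int = 1_500
    is_copy_count: int = 98
    duplicated_region_length: int = 0
    gc_target: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.is_copy_count < 0 or self.is_element_length <= 0:
            raise ValueError("invalid IS element parameters")
        if self.is_copy_count * self.is_element_length >= self.length:
            raise ValueError("IS copies do not fit in the genome")


@dataclass(frozen=True)
class ReadSimSpec:
    """Idealized paired-read simulation parameters (error-free)."""

    depth: float = 100.0
    read_length: int = 125
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if 2 * self.read_length > self.insert_mean + 4 * self.insert_sd:
            raise ValueError(
                "pair geometry infeasible: 2*read_length must not exceed "
                "insert_mean + 4*insert_sd")


@dataclass(frozen=True)
class SampleSpec:
    """A sample genome as edits of the reference.

    ``absent_is`` are indices of reference-annotated IS copies excised in
    the sample; ``novel_is`` are reference coordinates at which an extra
    IS copy is inserted (positions must fall in unique sequence).
    """

    name: str = "sample"
    absent_is: frozenset[int] = frozenset()
    novel_is: tuple[int, ...] = ()


@dataclass
class TruthTable:
    """Machine-readable planted truth for downstream recovery tests."""

    # (sample name, reference position, present-in-reference flag)
    planted_is_loci: list[tuple[str, int, bool]] = field(default_factory=list)
    planted_duplications: list[Interval] = field(default_factory=list)
    recombinant_gene_ids: set[str] = field(default_factory=set)
    branch_insertions: dict[str, int] = field(default_factory=dict)


# --- reference genome ----------------------------------------------------

def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


@dataclass
class Reference:
    """A simulated reference genome with annotated repeats."""

    genome: str
    annotation: list[Interval]          # IS copies and cassette copies
    is_consensus: str
    is_intervals: list[Interval]        # IS copies only, sorted
    cassette_intervals: list[Interval]  # 0 or 2 entries; [0]=kept, [1]=masked

    @property
    def length(self) -> int:
        return len(self.genome)

    def masked_genome(self, mask_cassette: bool = True) -> str:
        """All IS copies (and optionally the second cassette copy) -> N."""
        seq = np.array(list(self.genome))
        for iv in self.is_intervals:
            seq[iv.start:iv.end] = "N"
        if mask_cassette and len(self.cassette_intervals) == 2:
            iv = self.cassette_intervals[1]
            seq[iv.start:iv.end] = "N"
        return "".join(seq)

    def reference_lengths(self) -> dict[str, int]:
        return {GENOME: self.length, IS_CONSENSUS: len(self.is_consensus)}


def simulate_reference(spec: GenomeSpec) -> Reference:
    """Build genome sequence, repeat annotation and IS consensus.

    All planted IS copies are identical to the consensus (the collapsed-
    repeat idealization); the two cassette copies are identical to each
    other.  Feature placements are uniform in unique sequence and
    non-overlapping; infeasible packings raise ``ValueError``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n_is = spec.is_copy_count
    is_len = spec.is_element_length
    dup_len = spec.duplicated_region_length
    unique_len = spec.length - n_is * is_len - dup_len
    if unique_len <= max(dup_len, 0) or unique_len < n_is + 1:
        raise ValueError("features do not fit: genome packing infeasible")

    backbone = _random_seq(unique_len, spec.gc_target, rng)
    is_seq = _random_seq(is_len, spec.gc_target, rng)

    # cassette source on the backbone (original copy)
    cas_src = None
    if dup_len:
        src_start = int(rng.integers(0, unique_len - dup_len + 1))
        cas_src = (src_start, src_start + dup_len)

    # insertion points in backbone coordinates, outside the cassette source
    n_points = n_is + (1 if dup_len else 0)
    points: list[int] = []
    guard = 0
    while len(points) < n_points:
        guard += 1
        if guard > 100 * n_points + 1000:
            raise ValueError("could not place features without overlap")
        p = int(rng.integers(0, unique_len + 1))
        if cas_src and cas_src[0] < p < cas_src[1]:
            continue
        if p in points:
            continue
        points.append(p)
    is_points = sorted(points[:n_is])
    cas_point = points[n_is] if dup_len else None

    # assemble final genome, tracking feature intervals in final coords
    pieces: list[np.ndarray] = []
    is_intervals: list[Interval] = []
    cassette_intervals: list[Interval] = []
    events = sorted([(p, "IS") for p in is_points]
                    + ([(cas_point, "cassette")] if dup_len else []))
    cursor = 0
    out_pos = 0
    for p, kind in events:
        seg = backbone[cursor:p]
        pieces.append(seg)
        if cas_src and cursor <= cas_src[0] and cas_src[1] <= p:
            off = out_pos + (cas_src[0] - cursor)
            cassette_intervals.append(
                Interval(GENOME, off, off + dup_len, "cassette"))
        out_pos += len(seg)
        if kind == "IS":
            pieces.append(is_seq)
            is_intervals.append(Interval(GENOME, out_pos, out_pos + is_len, "IS"))
            out_pos += is_len
        else:
            pieces.append(backbone[cas_src[0]:cas_src[1]])
            cassette_intervals.append(
                Interval(GENOME, out_pos, out_pos + dup_len, "cassette"))
            out_pos += dup_len
        cursor = p
    seg = backbone[cursor:]
    pieces.append(seg)
    if cas_src and cursor <= cas_src[0]:
        off = out_pos + (cas_src[0] - cursor)
        cassette_intervals.append(
            Interval(GENOME, off, off + dup_len, "cassette"))
    genome = "".join("".join(p) for p in pieces)
    assert len(genome) == spec.length

    if dup_len:
        # keep the original copy unmasked, mask the inserted one
        cassette_intervals.sort(key=lambda iv: iv.start)
        a, b = cassette_intervals
        src = a if genome[a.start:a.end] == "".join(backbone[cas_src[0]:cas_src[1]]) else b
        other = b if src is a else a
        cassette_intervals = [src, other]

    annotation = sorted(is_intervals + cassette_intervals,
                        key=lambda iv: iv.start)
    return Reference(genome=genome, annotation=annotation,
                     is_consensus="".join(is_seq),
                     is_intervals=is_intervals,
                     cassette_intervals=cassette_intervals)


# --- sample genomes and provenance blocks --------------------------------

@dataclass(frozen=True)
class _Block:
    """A run of sample sequence with a single mapping provenance."""

    sample_start: int
    length: int
    target: str        # GENOME or IS_CONSENSUS
    target_start: int  # position on the target where the block maps


def _sample_blocks(ref: Reference, sample: SampleSpec,
                   mask_cassette: bool = True) -> list[_Block]:
    """Provenance block map of a sample genome against the masked reference."""
    for p in sample.novel_is:
        for iv in ref.annotation:
            if iv.start <= p < iv.end:
                raise ValueError(
                    f"novel IS position {p} falls inside an annotated repeat")
    # reference-coordinate breakpoints: IS copies (masked -> consensus),
    # masked cassette copy (-> unmasked copy), rest -> itself.
    features: list[tuple[int, int, str, int]] = []  # start, end, target, tstart
    for i, iv in enumerate(ref.is_intervals):
        if i in sample.absent_is:
            features.append((iv.start, iv.end, "deleted", 0))
        else:
            features.append((iv.start, iv.end, IS_CONSENSUS, 0))
    if mask_cassette and len(ref.cassette_intervals) == 2:
        kept, masked = ref.cassette_intervals
        features.append((masked.start, masked.end, GENOME, kept.start))
    features.sort()

    novel = sorted(sample.novel_is)
    blocks: list[_Block] = []
    sample_pos = 0

    def emit_ref_run(ref_start: int, ref_end: int) -> None:
        nonlocal sample_pos
        cursor = ref_start
        for p in novel:
            if ref_start <= p <= ref_end and cursor <= p:
                if p > cursor:
                    blocks.append(_Block(sample_pos, p - cursor, GENOME, cursor))
                    sample_pos += p - cursor
                blocks.append(_Block(sample_pos, len(ref.is_consensus),
                                     IS_CONSENSUS, 0))
                sample_pos += len(ref.is_consensus)
                cursor = p
        if ref_end > cursor:
            blocks.append(_Block(sample_pos, ref_end - cursor, GENOME, cursor))
            sample_pos += ref_end - cursor

    cursor = 0
    for start, end, target, tstart in features:
        if start > cursor:
            emit_ref_run(cursor, start)
        if target == "deleted":
            pass
        else:
            blocks.append(_Block(sample_pos, end - start, target,
                                 tstart if target == GENOME else 0))
            sample_pos += end - start
        cursor = end
    if cursor < ref.length:
        emit_ref_run(cursor, ref.length)
    return blocks


def _map_interval(blocks: list[_Block], starts: list[int], sample_len: int,
                  lo: int, hi: int) -> list[tuple[str, int, int]]:
    """Map a sample interval [lo, hi) to (target, tpos, length) segments.

    The interval may wrap around the circular origin.
    """
    segs: list[tuple[str, int, int]] = []
    spans = [(lo % sample_len, hi - lo)] if hi - lo <= sample_len else None
    if spans is None:
        raise ValueError("fragment longer than genome")
    s, n = spans[0]
    pieces = [(s, min(n, sample_len - s))]
    if n > sample_len - s:
        pieces.append((0, n - (sample_len - s)))
    for ps, pn in pieces:
        i = bisect_right(starts, ps) - 1
        pos = ps
        remaining = pn
        while remaining > 0:
            b = blocks[i]
            off = pos - b.sample_start
            take = min(remaining, b.length - off)
            segs.append((b.target, b.target_start + off, take))
            remaining -= take
            pos += take
            i += 1
    return segs


# --- read-pair simulation ------------------------------------------------

def simulate_pair_alignments(ref: Reference, sample: SampleSpec,
                             sim: ReadSimSpec,
                             mask_cassette: bool = True,
                             mapq: int = 60) -> list[AlignmentRecord]:
    """Render idealized SAM records of a sample's paired reads.

    Fragments are drawn uniformly along the circular sample genome with
    Normal(insert_mean, insert_sd) insert sizes (rounded, floored at the
    read length).  Each mate is decomposed by provenance; the longest
    segment is the primary record, shorter ones become supplementary
    records (depth conservation in lieu of soft-clipping).
    """
    blocks = _sample_blocks(ref, sample, mask_cassette)
    starts = [b.sample_start for b in blocks]
    sample_len = blocks[-1].sample_start + blocks[-1].length
    rl = sim.read_length
    if sim.insert_mean > sample_len:
        raise ValueError("fragment longer than genome")

    rng = np.random.default_rng(
        np.random.SeedSequence([sim.seed, 1, _name_key(sample.name)]))
    n_frag = int(round(sim.depth * sample_len / (2 * rl)))
    frag_starts = rng.integers(0, sample_len, size=n_frag)
    inserts = np.rint(rng.normal(sim.insert_mean, sim.insert_sd,
                                 size=n_frag)).astype(np.int64)
    inserts = np.clip(inserts, rl, sample_len)

    lo, hi = sim.insert_mean - 4 * sim.insert_sd, sim.insert_mean + 4 * sim.insert_sd
    records: list[AlignmentRecord] = []
    for k in range(n_frag):
        s = int(frag_starts[k])
        insert = int(inserts[k])
        qname = f"{sample.name}:frag{k}"
        r1 = _map_interval(blocks, starts, sample_len, s, s + rl)
        r2 = _map_interval(blocks, starts, sample_len,
                           s + insert - rl, s + insert)
        p1 = max(range(len(r1)), key=lambda i: r1[i][2])
        p2 = max(range(len(r2)), key=lambda i: r2[i][2])
        t1, pos1, len1 = r1[p1]
        t2, pos2, len2 = r2[p2]
        if t1 == t2:
            left = min(pos1, pos2)
            right = max(pos1 + len1, pos2 + len2)
            span = right - left
            tlen1 = span if pos1 <= pos2 else -span
            tlen2 = -tlen1
            proper = lo <= span <= hi
        else:
            tlen1 = tlen2 = 0
            proper = False
        for (reads, primary, target, tpos, tlen, is_read1, is_rev,
             m_target, m_pos) in (
                (r1, p1, t1, pos1, tlen1, True, False, t2, pos2),
                (r2, p2, t2, pos2, tlen2, False, True, t1, pos1)):
            for i, (tg, tp, ln) in enumerate(reads):
                records.append(AlignmentRecord(
                    qname=qname, ref=tg, pos=tp, length=ln, mapq=mapq,
                    tlen=tlen if i == primary else 0,
                    is_read1=is_read1, is_reverse=is_rev,
                    proper_pair=proper if i == primary else False,
                    mate_ref=m_target, mate_pos=m_pos,
                    supplementary=i != primary))
    return records


def _name_key(name: str) -> int:
    # stable small integer per sample name for seed spawning
    return sum(ord(c) * (i + 1) for i, c in enumerate(name)) % (2**16)


# --- planting insertions on a phylogeny ----------------------------------

def plant_insertions_on_tree(tree: dendropy.Tree, ref: Reference,
                             n_insertions: int, seed: int,
                             min_separation: int = 4000,
                             feature_clearance: int = 2500,
                             ) -> tuple[dict[str, SampleSpec], TruthTable]:
    """Plant post-divergence IS insertions on branches of a rooted tree.

    Each insertion is assigned to a uniformly drawn non-root branch and
    inherited by every leaf below it.  Insertion positions are drawn in
    unique sequence, pairwise separated by ``min_separation`` and at least
    ``feature_clearance`` from annotated repeats, so read-pair evidence
    clusters stay unambiguous.  Returns per-leaf sample specs and a truth
    table with per-branch insertion counts (branch id = bipartition of
    leaf names below the branch, comma-joined and sorted).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    edges = [e for e in tree.preorder_edge_iter()
             if e.head_node is not tree.seed_node]
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]

    blocked: list[tuple[int, int]] = [
        (iv.start - feature_clearance, iv.end + feature_clearance)
        for iv in ref.annotation]
    positions: list[int] = []
    guard = 0
    while len(positions) < n_insertions:
        guard += 1
        if guard > 10_000:
            raise ValueError("could not place insertions with the requested "
                             "separation")
        p = int(rng.integers(feature_clearance,
                             ref.length - feature_clearance))
        if any(lo <= p < hi for lo, hi in blocked):
            continue
        if any(abs(p - q) < min_separation for q in positions):
            continue
        positions.append(p)

    truth = TruthTable()
    novel_by_leaf: dict[str, list[int]] = {lf: [] for lf in leaves}
    for p in positions:
        edge = edges[int(rng.integers(len(edges)))]
        below = sorted(lf.taxon.label
                       for lf in edge.head_node.leaf_iter())
        branch_id = ",".join(below)
        truth.branch_insertions[branch_id] = (
            truth.branch_insertions.get(branch_id, 0) + 1)
        for lf in below:
            novel_by_leaf[lf].append(p)
            truth.planted_is_loci.append((lf, p, False))
    samples = {lf: SampleSpec(name=lf, novel_is=tuple(sorted(novel_by_leaf[lf])))
               for lf in leaves}
    return samples, truth


# --- gene alignment simulation -------------------------------------------

def simulate_gene_alignments(tree_main: dendropy.Tree,
                             tree_alt: dendropy.Tree,
                             n_genes: int,
                             recomb_fraction: float,
                             gene_length: int,
                             subst_scale: float,
                             seed: int,
                             ) -> tuple[dict[str, dict[str, str]], TruthTable]:
    """Evolve gene alignments; a fixed fraction are two-topology chimeras.

    Non-recombinant genes evolve on ``tree_main`` under Jukes-Cantor
    (independent sites, single rate, uniform base frequencies) with branch
    lengths multiplied by ``subst_scale``.  Recombinant genes concatenate
    two half-length segments evolved on ``tree_main`` and ``tree_alt``.
    Returns ``{gene_id: {taxon: sequence}}`` and the truth table marking
    recombinant gene ids.  The first ``round(n_genes * recomb_fraction)``
    genes (by index) are the recombinants.
    """
    if not 0.0 <= recomb_fraction <= 1.0:
        raise ValueError("recomb_fraction must be in [0, 1]")
    taxa_main = {t.label for t in tree_main.taxon_namespace}
    taxa_alt = {t.label for t in tree_alt.taxon_namespace}
    if taxa_main != taxa_alt:
        raise ValueError("trees must share the taxon set")

    n_recomb = int(round(n_genes * recomb_fraction))
    truth = TruthTable()
    alignments: dict[str, dict[str, str]] = {}
    pyrng = random.Random(seed)
    for g in range(n_genes):
        gene_id = f"gene{g:04d}"
        if g < n_recomb:
            half = gene_length // 2
            seg1 = _evolve(tree_main, half, subst_scale, pyrng)
            seg2 = _evolve(tree_alt, gene_length - half, subst_scale, pyrng)
            aln = {tax: seg1[tax] + seg2[tax] for tax in seg1}
            truth.recombinant_gene_ids.add(gene_id)
        else:
            aln = _evolve(tree_main, gene_length, subst_scale, pyrng)
        alignments[gene_id] = aln
    return alignments, truth


def _evolve(tree: dendropy.Tree, n_sites: int, scale: float,
            pyrng: random.Random) -> dict[str, str]:
    if n_sites <= 0:
        raise ValueError("gene_length too small")
    if scale == 0.0:
        # degenerate process: identical sequences, still seeded draws
        seq = "".join(pyrng.choice("ACGT") for _ in range(n_sites))
        return {t.label: seq for t in tree.taxon_namespace}
    mat = _discrete.simulate_discrete_chars(
        n_sites, tree, _discrete.Jc69(), mutation_rate=scale, rng=pyrng)
    return {taxon.label: str(mat[taxon]) for taxon in mat}


# --- FASTA helpers --------------------------------------------------------

def write_fasta(path: str, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
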