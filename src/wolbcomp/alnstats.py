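"""Alignment bookkeeping: gap pruning, back-translation, concatenation,
parsimony-informative sites and the orthology pair filter.

An MSA is a mapping of sequence id to aligned row (equal lengths).  Gaps
are ``-``; ambiguity codes (``N``/``X``) are treated as missing when
counting character states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

GAP_CHARS = set("-.")
AMBIGUOUS = set("NXnx?")

_CODON_TABLE_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class MSA:
    """A multiple sequence alignment with unique ids and equal row lengths."""

    sequences: dict[str, str]
    alphabet: str = "nucleotide"  # or "amino-acid"

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: unequal row lengths")

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def column(self, i: int) -> list[str]:
        return [s[i] for s in self.sequences.values()]


@dataclass(frozen=True)
class PartitionedSupermatrix:
    msa: MSA
    partitions: dict[str, tuple[int, int]]  # gene id -> half-open column range


def prune_gap_columns(msa: MSA, max_gap_fraction: float = 0.5
                      ) -> tuple[MSA, list[int]]:
    """Remove columns whose gap fraction strictly exceeds the cutoff.

    Returns the pruned MSA and the provenance map: original column index
    of each retained column.
    """
    n = len(msa.sequences)
    if n == 0:
        raise ValueError("empty alignment")
    keep: list[int] = []
    rows = list(msa.sequences.values())
    for i in range(msa.n_columns):
        gaps = sum(1 for row in rows if row[i] in GAP_CHARS)
        if gaps / n <= max_gap_fraction:
            keep.append(i)
    pruned = {sid: "".join(seq[i] for i in keep)
              for sid, seq in msa.sequences.items()}
    return MSA(pruned, msa.alphabet), keep


def backtranslate(protein_msa: MSA, cds_sequences: dict[str, str]) -> MSA:
    """Expand an amino-acid alignment to a codon alignment.

    Each CDS must be 3x the ungapped protein length; a single trailing
    stop codon is stripped, internal stops are an error.  Protein gaps
    become codon gaps (``---``).
    """
    out: dict[str, str] = {}
    for sid, prot in protein_msa.sequences.items():
        if sid not in cds_sequences:
            raise ValueError(f"no CDS for sequence {sid!r}")
        cds = cds_sequences[sid].upper().replace("U", "T")
        n_aa = sum(1 for c in prot if c not in GAP_CHARS)
        if len(cds) == 3 * (n_aa + 1) and cds[-3:] in _CODON_TABLE_STOPS:
            cds = cds[:-3]
        if len(cds) != 3 * n_aa:
            raise ValueError(
                f"CDS length mismatch for {sid!r}: {len(cds)} nt vs "
                f"{n_aa} residues")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        for j, codon in enumerate(codons[:-1]):
            if codon in _CODON_TABLE_STOPS:
                raise ValueError(f"internal stop codon in {sid!r} at codon {j}")
        it = iter(codons)
        out[sid] = "".join("---" if c in GAP_CHARS else next(it)
                           for c in prot)
    return MSA(out, "nucleotide")


def count_informative_sites(msa: MSA) -> tuple[int, int, float]:
    """Parsimony-informative site count, total columns, and fraction.

    A column is informative iff at least two distinct states each occur
    in at least two sequences; gaps and ambiguity codes do not count as
    states.
    """
    rows = list(msa.sequences.values())
    total = msa.n_columns
    informative = 0
    for i in range(total):
        counts: dict[str, int] = {}
        for row in rows:
            c = row[i].upper()
            if c in GAP_CHARS or c in AMBIGUOUS:
                continue
            counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    fraction = informative / total if total else 0.0
    return informative, total, fraction


def concatenate(alignments: dict[str, MSA]) -> PartitionedSupermatrix:
    """Concatenate gene alignments into a partitioned supermatrix.

    Taxa absent from a gene are padded with gaps over that partition.
    """
    if len(alignments) == 0:
        raise ValueError("no alignments to concatenate")
    gene_ids = list(alignments)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    taxa: list[str] = []
    for msa in alignments.values():
        for sid in msa.ids:
            if sid not in taxa:
                taxa.append(sid)
    alphabet = next(iter(alignments.values())).alphabet
    parts: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    offset = 0
    for gid, msa in alignments.items():
        width = msa.n_columns
        parts[gid] = (offset, offset + width)
        for t in taxa:
            rows[t].append(msa.sequences.get(t, "-" * width))
        offset += width
    concat = MSA({t: "".join(chunks) for t, chunks in rows.items()}, alphabet)
    return PartitionedSupermatrix(concat, parts)


@dataclass(frozen=True)
class ProteinPairHit:
    """A reciprocal-protein homology hit with both sequence lengths."""

    id_a: str
    id_b: str
    len_a: int
    len_b: int
    evalue: float
    alignment_length: int


def filter_homology_pairs(hits: Sequence[ProteinPairHit]
                          ) -> list[ProteinPairHit]:
    """Orthology pre-filter on protein pair hits.

    Kept iff the shorter protein is at least 60% the length of the
    longer, evalue < 1e-5 (strict), and the alignment covers at least
    80% of the shorter protein.
    """
    kept = []
    for h in hits:
        shorter, longer = min(h.len_a, h.len_b), max(h.len_a, h.len_b)
        if (shorter / longer >= 0.6 and h.evalue < 1e-5
                and h.alignment_length >= 0.8 * shorter):
            kept.append(h)
    return kept


# --- FASTA / partition I/O ----------------------------------------------

def read_msa(path: str, alphabet: str = "nucleotide") -> MSA:
    from Bio import SeqIO
    return MSA({rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")},
               alphabet)


def write_msa(path: str, msa: MSA, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in msa.sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_partitions(path: str, sm: PartitionedSupermatrix,
                     datatype: str = "DNA") -> None:
    """RAxML-style plain-text partition table (1-based inclusive)."""
    with open(path, "w") as fh:
        for gid, (start, end) in sm.partitions.items():
            fh.write(f"{datatype}, {gid} = {start + 1}-{end}\n")
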