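"""IS insertion/absence calling from improper read pairs.

Against a reference in which every IS copy is masked and one consensus
copy is appended as a separate sequence, read pairs carry three kinds of
structural evidence:

* **shared insertion** -- TLEN = 0 with one mate on the consensus and the
  genome mate within ``flank`` (default 750 bp) of a reference-annotated
  IS boundary: the sample carries the same IS copy as the reference.
* **novel insertion** -- the same signature away from any annotated IS:
  the sample carries an IS copy the reference lacks.
* **absence** -- both mates on the genome, improper, with
  ``tlen_lo < |TLEN| < tlen_hi`` (defaults 1500/5000, strict) and
  flanking an annotated IS: the sample lacks that reference copy, so the
  apparent insert is inflated by roughly the element length.

Proper pairs and MAPQ < 1 reads are discarded first.  Evidence is
clustered into loci, thresholded at ``min_support`` pairs, and assembled
into a loci x samples presence/absence matrix; reference-annotated loci
without contradicting evidence are imputed ``present`` (complete IS
excisions are rare) when flank depth suffices, otherwise ``unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .coverage import Interval
from .samio import AlignmentRecord

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"

EV_SHARED = "shared_insertion"
EV_NOVEL = "novel_insertion"
EV_ABSENCE = "absence"
EV_NONE = "none"


@dataclass(frozen=True)
class ISLocus:
    contig: str
    start: int
    end: int
    status_in_reference: str  # "annotated" | "novel"
    shared_support: int = 0
    novel_support: int = 0
    absence_support: int = 0
    call: str = UNKNOWN


@dataclass(frozen=True)
class Evidence:
    qname: str
    cls: str
    position: int              # genome-mate leftmost position
    locus_index: Optional[int]  # annotated locus index, if applicable


def _near_annotated(pos: int, end: int, annotation: Sequence[Interval],
                    flank: int) -> Optional[int]:
    """Index of an annotated IS whose flanked interval overlaps [pos, end)."""
    for i, iv in enumerate(annotation):
        if pos < iv.end + flank and end > iv.start - flank:
            return i
    return None


def classify_pair(rec: AlignmentRecord, is_annotation: Sequence[Interval],
                  flank: int = 750, tlen_lo: int = 1500,
                  tlen_hi: int = 5000, min_mapq: int = 1,
                  genome: str = "genome",
                  is_consensus: str = "IS_consensus") -> str:
    """Evidence class of one genome-side alignment record.

    Classification is per record: the genome-mapped mate of a cross-
    reference pair carries the insertion evidence; consensus-side and
    supplementary records classify as ``none``.
    """
    if rec.qname == "" or rec.length <= 0:
        raise ValueError(f"malformed record {rec.qname!r}")
    if (rec.supplementary or rec.unmapped or rec.mate_unmapped
            or rec.proper_pair or rec.mapq < min_mapq):
        return EV_NONE
    if rec.ref != genome:
        return EV_NONE
    if rec.mate_ref == is_consensus:
        # TLEN is 0 by convention for cross-reference pairs
        near = _near_annotated(rec.pos, rec.end, is_annotation, flank)
        return EV_SHARED if near is not None else EV_NOVEL
    if rec.mate_ref == genome and tlen_lo < abs(rec.tlen) < tlen_hi:
        if _near_annotated(rec.pos, rec.end, is_annotation, flank) is not None:
            return EV_ABSENCE
    return EV_NONE


def _attribute_shared(rec: AlignmentRecord, annotation: Sequence[Interval],
                      flank: int) -> Optional[int]:
    """Annotated IS a shared-insertion mate points at.

    The consensus-mapped partner of a forward genome mate lies downstream,
    so the element boundary is the nearest annotated start at or beyond
    the read; for a reverse mate it is the nearest end at or before the
    read's end.  Directional attribution keeps evidence from bleeding
    onto a neighbouring copy when two elements sit closer than 2*flank.
    """
    if not rec.is_reverse:
        cands = [(iv.start, i) for i, iv in enumerate(annotation)
                 if iv.start >= rec.pos and iv.start - rec.end <= flank]
        return min(cands)[1] if cands else None
    cands = [(-iv.end, i) for i, iv in enumerate(annotation)
             if iv.end <= rec.end and rec.pos - iv.end <= flank]
    return min(cands)[1] if cands else None


def _spanned_annotated(rec: AlignmentRecord, annotation: Sequence[Interval]
                       ) -> Optional[int]:
    """Annotated IS contained in the template span of an absence pair."""
    left = min(rec.pos, rec.pos + rec.tlen)
    right = max(rec.pos, rec.pos + rec.tlen)
    for i, iv in enumerate(annotation):
        if left <= iv.start and iv.end <= right:
            return i
    return None


def classify_evidence(records: Sequence[AlignmentRecord],
                      is_annotation: Sequence[Interval],
                      flank: int = 750, tlen_lo: int = 1500,
                      tlen_hi: int = 5000, min_mapq: int = 1,
                      genome: str = "genome",
                      is_consensus: str = "IS_consensus") -> list[Evidence]:
    """One :class:`Evidence` per informative read pair.

    Order-independent: the multiset of evidence depends only on the set
    of records.  Absence pairs (two genome-side records) are deduplicated
    by query name, keeping the leftmost (TLEN > 0) side.
    """
    out: dict[tuple[str, str], Evidence] = {}
    for rec in records:
        cls = classify_pair(rec, is_annotation, flank, tlen_lo, tlen_hi,
                            min_mapq, genome, is_consensus)
        if cls == EV_NONE:
            continue
        if cls == EV_ABSENCE:
            if rec.tlen < 0:
                continue  # count each pair once, from its left record
            locus = _spanned_annotated(rec, is_annotation)
            if locus is None:
                continue
        elif cls == EV_SHARED:
            locus = _attribute_shared(rec, is_annotation, flank)
            if locus is None:
                locus = _near_annotated(rec.pos, rec.end, is_annotation,
                                        flank)
        else:
            locus = None
        out[(rec.qname, cls)] = Evidence(rec.qname, cls, rec.pos, locus)
    return sorted(out.values(), key=lambda e: (e.cls, e.position, e.qname))


def call_loci(evidence: Sequence[Evidence],
              is_annotation: Sequence[Interval],
              min_support: int = 3, cluster_window: int = 500,
              contig: str = "genome") -> list[ISLocus]:
    """Aggregate evidence into per-locus calls for one sample.

    Novel-insertion evidence is clustered by genome-mate position (single
    linkage, gap <= ``cluster_window``); a cluster with >= ``min_support``
    pairs is a present novel locus.  An annotated locus is ``absent``
    with >= ``min_support`` absence pairs and fewer shared pairs,
    ``present`` in the converse case, and ``unknown`` when evidence
    conflicts or is insufficient.
    """
    shared = [0] * len(is_annotation)
    absence = [0] * len(is_annotation)
    novel_positions: list[int] = []
    for ev in evidence:
        if ev.cls == EV_SHARED and ev.locus_index is not None:
            shared[ev.locus_index] += 1
        elif ev.cls == EV_ABSENCE and ev.locus_index is not None:
            absence[ev.locus_index] += 1
        elif ev.cls == EV_NOVEL:
            novel_positions.append(ev.position)

    loci: list[ISLocus] = []
    for i, iv in enumerate(is_annotation):
        s, a = shared[i], absence[i]
        if s >= min_support and a < min_support:
            call = PRESENT
        elif a >= min_support and s < min_support:
            call = ABSENT
        else:
            call = UNKNOWN
        loci.append(ISLocus(contig, iv.start, iv.end, "annotated",
                            shared_support=s, absence_support=a, call=call))

    novel_positions.sort()
    cluster: list[int] = []
    for pos in novel_positions + [None]:  # type: ignore[list-item]
        if pos is not None and (not cluster
                                or pos - cluster[-1] <= cluster_window):
            cluster.append(pos)
            continue
        if cluster and len(cluster) >= min_support:
            loci.append(ISLocus(contig, cluster[0], cluster[-1] + 1, "novel",
                                novel_support=len(cluster), call=PRESENT))
        cluster = [pos] if pos is not None else []
    return loci


def build_presence_matrix(calls_by_sample: Mapping[str, Sequence[ISLocus]],
                          is_annotation: Sequence[Interval],
                          cluster_window: int = 500,
                          flank_depth: Optional[Mapping[str, float]] = None,
                          min_flank_depth: float = 5.0) -> pd.DataFrame:
    """Loci x samples matrix over {present, absent, unknown}.

    Rows are the reference-annotated loci plus novel loci unified across
    samples by position overlap within ``cluster_window``.  Annotated
    loci without evidence in a sample default to the reference state
    (present) when that sample's flank depth reaches
    ``min_flank_depth`` (always assumed when ``flank_depth`` is None);
    novel loci without evidence default to absent under the same depth
    condition.  Row ids are stable across runs.
    """
    samples = list(calls_by_sample)

    def depth_ok(sample: str) -> bool:
        if flank_depth is None:
            return True
        return flank_depth.get(sample, 0.0) >= min_flank_depth

    # unify novel loci across samples
    novel_events: list[tuple[int, int, str, ISLocus]] = []
    for sample in samples:
        for locus in calls_by_sample[sample]:
            if locus.status_in_reference == "novel":
                novel_events.append((locus.start, locus.end, sample, locus))
    novel_events.sort()
    unified: list[tuple[int, int, dict[str, str]]] = []
    for start, end, sample, locus in novel_events:
        if unified and start - unified[-1][1] <= cluster_window:
            prev = unified[-1]
            unified[-1] = (prev[0], max(prev[1], end),
                           {**prev[2], sample: locus.call})
        else:
            unified.append((start, end, {sample: locus.call}))

    rows = {}
    for i, iv in enumerate(is_annotation):
        row_id = f"ref_{i:03d}_{iv.start}"
        row = {}
        for sample in samples:
            call = next((l.call for l in calls_by_sample[sample]
                         if l.status_in_reference == "annotated"
                         and l.start == iv.start), UNKNOWN)
            if call == UNKNOWN:
                has_evidence = any(
                    l.start == iv.start and (l.shared_support or
                                             l.absence_support)
                    for l in calls_by_sample[sample]
                    if l.status_in_reference == "annotated")
                if not has_evidence:
                    call = PRESENT if depth_ok(sample) else UNKNOWN
            row[sample] = call
        rows[row_id] = row
    for start, end, calls in unified:
        row_id = f"novel_{start}"
        rows[row_id] = {
            sample: calls.get(sample,
                              ABSENT if depth_ok(sample) else UNKNOWN)
            for sample in samples}

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return matrix


def write_matrix_tsv(path: str, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="locus")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus")
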