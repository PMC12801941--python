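"""Lightweight alignment records and SAM text I/O.

The whole pipeline operates on idealized mapper output: read pairs placed
on a masked endosymbiont genome and/or a transposable-element consensus
sequence.  Records carry only the SAM fields the downstream evidence rules
use (FLAG, RNAME, POS, MAPQ, RNEXT, PNEXT, TLEN).  Alignments are gapless
spans (CIGAR ``<n>M``); read portions that derive from a different
reference sequence are emitted as separate supplementary records instead
of soft-clips, so per-base depth is conserved across reference sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment of a read, in 0-based half-open coordinates.

    ``tlen`` follows the SAM sign convention: positive on the leftmost
    mate, negative on the rightmost, and 0 when the mates map to
    different reference sequences.
    """

    qname: str
    ref: str
    pos: int          # 0-based leftmost aligned base
    length: int       # aligned span on the reference
    mapq: int
    tlen: int
    is_read1: bool
    is_reverse: bool
    proper_pair: bool
    mate_ref: str
    mate_pos: int     # 0-based
    mate_unmapped: bool = False
    unmapped: bool = False
    supplementary: bool = False

    @property
    def end(self) -> int:
        return self.pos + self.length

    @property
    def flag(self) -> int:
        f = FLAG_PAIRED
        if self.proper_pair:
            f |= FLAG_PROPER
        if self.unmapped:
            f |= FLAG_UNMAPPED
        if self.mate_unmapped:
            f |= FLAG_MATE_UNMAPPED
        if self.is_reverse:
            f |= FLAG_REVERSE
        else:
            f |= FLAG_MATE_REVERSE
        f |= FLAG_READ1 if self.is_read1 else FLAG_READ2
        if self.supplementary:
            f |= FLAG_SUPPLEMENTARY
        return f


def write_sam(path: str, records: Iterable[AlignmentRecord],
              reference_lengths: dict[str, int]) -> None:
    """Write records as headered SAM text (SEQ/QUAL omitted)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length}
               for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = rec.flag
            a.reference_id = out.header.get_tid(rec.ref)
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = f"{rec.length}M"
            a.next_reference_id = out.header.get_tid(rec.mate_ref)
            a.next_reference_start = rec.mate_pos
            a.template_length = rec.tlen
            out.write(a)


def read_sam(path: str) -> list[AlignmentRecord]:
    """Parse SAM text back into :class:`AlignmentRecord` objects."""
    records = []
    with pysam.AlignmentFile(path, "r") as sam:
        for a in sam:
            records.append(AlignmentRecord(
                qname=a.query_name,
                ref=a.reference_name if not a.is_unmapped else "*",
                pos=a.reference_start,
                length=a.reference_length or 0,
                mapq=a.mapping_quality,
                tlen=a.template_length,
                is_read1=a.is_read1,
                is_reverse=a.is_reverse,
                proper_pair=a.is_proper_pair,
                mate_ref=(a.next_reference_name
                          if not a.mate_is_unmapped else "*"),
                mate_pos=a.next_reference_start,
                mate_unmapped=a.mate_is_unmapped,
                unmapped=a.is_unmapped,
                supplementary=a.is_supplementary,
            ))
    return records


def primary_records(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Drop supplementary segments, keeping one record per mate."""
    return [r for r in records if not r.supplementary]
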