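"""Interval arithmetic, depth profiling and coverage-ratio copy number.

Collapsed-repeat copy number is estimated exactly as in a masked-reference
mapping experiment: every copy of a repeat is masked in the reference, one
consensus copy is kept, and the mean read depth over the consensus divided
by the mean depth over unique (non-repeat) sequence estimates the copy
count.  A cassette duplicated twice in the sample but present once in the
reference shows a ratio of ~2.

Intervals are 0-based half-open (BED convention); SAM positions are
converted to 0-based at parse time.  Depth is counted from whole aligned
spans -- clipped alignments are represented upstream as separate
supplementary segments, so per-base depth is conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .samio import AlignmentRecord


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageSummary:
    label: str
    mean: float
    sd: float
    n_bases: int


@dataclass(frozen=True)
class CopyNumberEstimate:
    target: str
    ratio: float
    background_mean: float
    background_cv: float
    call: str  # single | duplicated | multi(k) | inconclusive


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals per contig; sorted output."""
    out: list[Interval] = []
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(contig, cur_s, cur_e))
    return out


def interval_complement(intervals: Sequence[Interval],
                        contig_lengths: dict[str, int]) -> list[Interval]:
    """Complement of the merged input over each contig (bedtools-style)."""
    for iv in intervals:
        if iv.contig not in contig_lengths:
            raise ValueError(f"unknown contig {iv.contig!r}")
        if iv.end > contig_lengths[iv.contig]:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds length of {iv.contig}")
    merged = merge_intervals(intervals)
    out: list[Interval] = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        pos = 0
        for iv in (i for i in merged if i.contig == contig):
            if iv.start > pos:
                out.append(Interval(contig, pos, iv.start))
            pos = iv.end
        if pos < length:
            out.append(Interval(contig, pos, length))
    return out


def depth_array(records: Iterable[AlignmentRecord], contig: str,
                contig_length: int, min_mapq: int = 1) -> np.ndarray:
    """Per-base depth over one contig from whole aligned spans."""
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for rec in records:
        if rec.ref != contig or rec.unmapped or rec.mapq < min_mapq:
            continue
        diff[rec.pos] += 1
        diff[min(rec.end, contig_length)] -= 1
    return np.cumsum(diff[:-1])


def mean_depth(records: Sequence[AlignmentRecord],
               intervals: Sequence[Interval],
               contig_lengths: dict[str, int],
               min_mapq: int = 1,
               label: str = "") -> CoverageSummary:
    """Mean/sd per-base depth over the union of ``intervals``.

    Reads below ``min_mapq`` are excluded (the default of 1 drops
    MAPQ-0 multi-mappers, mirroring an ``MQ < 1`` filter).
    """
    merged = merge_intervals(intervals)
    if not merged:
        raise ValueError("empty interval set")
    contigs = {iv.contig for iv in merged}
    values: list[np.ndarray] = []
    for contig in sorted(contigs):
        depth = depth_array(records, contig, contig_lengths[contig], min_mapq)
        for iv in merged:
            if iv.contig == contig:
                values.append(depth[iv.start:iv.end])
    allv = np.concatenate(values)
    return CoverageSummary(label=label, mean=float(allv.mean()),
                           sd=float(allv.std()), n_bases=int(allv.size))


def duplication_call(ratio: float, background_cv: float,
                     dup_lo: float = 1.75, single_hi: float = 1.25,
                     max_cv: float = 0.15) -> str:
    """Binary duplication decision from a coverage ratio.

    A target is called ``duplicated`` when its depth is close to twice the
    unique-sequence depth and the background is quiet; noisy backgrounds
    (coefficient of variation above ``max_cv``, as seen when unique-region
    coverage sd reaches ~30% of the mean) are inconclusive.
    """
    if not math.isfinite(ratio):
        raise ValueError("ratio must be finite")
    if background_cv > max_cv:
        return "inconclusive"
    if ratio >= dup_lo:
        return "duplicated"
    if ratio <= single_hi:
        return "single"
    return "inconclusive"


def copy_number(target: CoverageSummary,
                background: CoverageSummary) -> CopyNumberEstimate:
    """Coverage-ratio copy number of a collapsed repeat.

    ratio = mean depth over the consensus / mean depth over unique
    sequence.  Calls: ``single`` (ratio <= 1.25), ``duplicated``
    (1.75 <= ratio <= 2.25), ``multi(k)`` with k the nearest integer for
    larger ratios, otherwise ``inconclusive``; any call other than
    ``inconclusive`` requires background CV <= 0.15.
    """
    if background.mean <= 0:
        raise ValueError("background coverage is zero")
    ratio = target.mean / background.mean
    cv = background.sd / background.mean
    if cv > 0.15:
        call = "inconclusive"
    elif ratio <= 1.25:
        call = "single"
    elif ratio < 1.75:
        call = "inconclusive"
    elif ratio <= 2.25:
        call = "duplicated"
    else:
        call = f"multi({round(ratio)})"
    return CopyNumberEstimate(target=target.label, ratio=ratio,
                              background_mean=background.mean,
                              background_cv=cv, call=call)


# --- BED I/O -------------------------------------------------------------

def read_bed(path: str) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            intervals.append(Interval(parts[0], int(parts[1]), int(parts[2]),
                                      label))
    return intervals


def write_bed(path: str, intervals: Sequence[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.label:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")
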