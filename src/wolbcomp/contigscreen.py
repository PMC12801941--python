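"""Assembly-contig decontamination for endosymbiont draft genomes.

Draft assemblies of host-associated bacteria mix symbiont contigs with
host and environmental contamination.  Contigs are screened on four
signals, applied in a fixed order:

1. *k*-mer coverage: when log-coverage is bimodal (symbiont vs
   contaminant depth), the valley between the two modes is the cutoff.
2. Redundancy: low-coverage contigs that are near-identical to a kept
   contig are removed as redundant.
3. Homology rescue: remaining low-coverage contigs are kept only if a
   homology hit to a trusted database is long and similar enough
   (protein: >100 aa and >60% identity; nucleotide: >200 nt and >70%
   identity; strict inequalities).
4. GC content: contigs outside the central 99% interval of a normal fit
   to the sample's GC values are removed, as are contigs whose taxonomic
   label matches a blocklist (e.g. the host genus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HitRecord:
    """One homology hit (blast-style) attached to a contig."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    unit: str                 # "protein" or "nucleotide"
    evalue: float = 0.0

    def __post_init__(self):
        if self.alignment_length <= 0:
            raise ValueError("alignment_length must be positive")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.unit not in ("protein", "nucleotide"):
            raise ValueError(f"unknown hit unit {self.unit!r}")


@dataclass(frozen=True)
class ContigRecord:
    id: str
    length: int
    kmer_coverage: float
    gc: float
    homology_hits: tuple[HitRecord, ...] = ()
    taxon_label: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("contig length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.kmer_coverage < 0:
            raise ValueError("kmer_coverage must be >= 0")


class ThresholdStatus(Enum):
    OK = "ok"                # bimodal, threshold found
    UNIMODAL = "unimodal"    # no inter-peak minimum
    NO_TEST = "no_test"      # too few values to test


@dataclass(frozen=True)
class ThresholdResult:
    status: ThresholdStatus
    value: Optional[float] = None


def bimodal_threshold(coverages: Sequence[float],
                      grid_points: int = 512) -> ThresholdResult:
    """Valley of a bimodal log-coverage distribution, if any.

    A Gaussian KDE (Silverman bandwidth) is fitted to log-coverage.  If
    the density has two or more local maxima, the threshold is the
    coverage at the deepest local minimum between peaks; a unimodal
    density yields ``UNIMODAL`` and fewer than 10 values yield
    ``NO_TEST`` (no screening, as distinct from evidence of unimodality).
    """
    vals = np.asarray([c for c in coverages if c > 0], dtype=float)
    if vals.size < 10:
        return ThresholdResult(ThresholdStatus.NO_TEST)
    logv = np.log(vals)
    if np.ptp(logv) == 0:
        return ThresholdResult(ThresholdStatus.UNIMODAL)
    kde = stats.gaussian_kde(logv, bw_method="silverman")
    pad = 0.5
    grid = np.linspace(logv.min() - pad, logv.max() + pad, grid_points)
    dens = kde(grid)
    d = np.diff(dens)
    maxima = [i for i in range(1, len(dens) - 1)
              if d[i - 1] > 0 >= d[i]]
    if len(maxima) < 2:
        return ThresholdResult(ThresholdStatus.UNIMODAL)
    # deepest minimum between consecutive maxima
    best_val, best_dens = None, math.inf
    for a, b in zip(maxima[:-1], maxima[1:]):
        i = a + int(np.argmin(dens[a:b + 1]))
        if dens[i] < best_dens:
            best_dens = dens[i]
            best_val = grid[i]
    return ThresholdResult(ThresholdStatus.OK, float(np.exp(best_val)))


def gc_outlier_bounds(gc_values: Sequence[float],
                      level: float = 0.99) -> tuple[float, float]:
    """Central ``level`` interval of a normal fitted to the GC values."""
    vals = np.asarray(gc_values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 GC values")
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    if sd <= 1e-12 * max(abs(mu), 1.0):
        raise ValueError("zero spread in GC values: degenerate bounds")
    if level >= 1.0:
        return (-math.inf, math.inf)
    z = stats.norm.ppf(0.5 + level / 2)
    return (mu - z * sd, mu + z * sd)


def rescue_by_homology(hit: HitRecord) -> bool:
    """Keep a low-coverage contig on the strength of one homology hit.

    Protein hits must exceed 100 aa and 60% identity; nucleotide hits
    must exceed 200 nt and 70% identity (strict inequalities).
    """
    if hit.unit == "protein":
        return hit.alignment_length > 100 and hit.percent_identity > 60.0
    return hit.alignment_length > 200 and hit.percent_identity > 70.0


@dataclass
class FilterResult:
    kept: list[ContigRecord] = field(default_factory=list)
    removed: list[tuple[ContigRecord, str]] = field(default_factory=list)

    @property
    def removed_ids(self) -> dict[str, str]:
        return {c.id: reason for c, reason in self.removed}


def _is_redundant(contig: ContigRecord, others: dict[str, ContigRecord],
                  min_identity: float, min_cover: float) -> bool:
    for hit in contig.homology_hits:
        other = others.get(hit.subject_id)
        if other is None or other.id == contig.id:
            continue
        shorter = min(contig.length, other.length)
        if (hit.percent_identity >= min_identity
                and hit.alignment_length >= min_cover * shorter):
            return True
    return False


def filter_contigs(contigs: Sequence[ContigRecord],
                   coverage_threshold: Optional[float] = None,
                   gc_level: float = 0.99,
                   taxon_blocklist: Sequence[str] = (),
                   redundancy_identity: float = 95.0,
                   redundancy_cover: float = 0.9) -> FilterResult:
    """Partition contigs into kept / removed(reason).

    ``coverage_threshold=None`` applies :func:`bimodal_threshold` to the
    input coverages; a ``UNIMODAL``/``NO_TEST`` outcome disables the
    coverage rule.  Rule precedence per contig: redundancy -> homology
    rescue -> GC -> taxonomy; each removal carries one reason.
    """
    if coverage_threshold is None:
        res = bimodal_threshold([c.kmer_coverage for c in contigs])
        coverage_threshold = res.value if res.status is ThresholdStatus.OK else None

    try:
        gc_lo, gc_hi = gc_outlier_bounds([c.gc for c in contigs], gc_level)
    except ValueError:
        gc_lo, gc_hi = -math.inf, math.inf

    by_id = {c.id: c for c in contigs}
    blockset = {t.lower() for t in taxon_blocklist}
    result = FilterResult()
    for contig in contigs:
        reason = None
        if (coverage_threshold is not None
                and contig.kmer_coverage < coverage_threshold):
            if _is_redundant(contig, by_id, redundancy_identity,
                             redundancy_cover):
                reason = "redundant"
            elif not any(rescue_by_homology(h) for h in contig.homology_hits):
                reason = "low_coverage"
        if reason is None and not (gc_lo <= contig.gc <= gc_hi):
            reason = "gc_outlier"
        if reason is None and contig.taxon_label is not None \
                and contig.taxon_label.lower() in blockset:
            reason = "taxonomy"
        if reason is None:
            result.kept.append(contig)
        else:
            result.removed.append((contig, reason))
    return result


# --- tabular I/O ---------------------------------------------------------

def read_blast_tsv(path: str, unit: str = "nucleotide") -> list[HitRecord]:
    """12-column blast-style TSV (qseqid sseqid pident length ... evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(HitRecord(query_id=f[0], subject_id=f[1],
                                  percent_identity=float(f[2]),
                                  alignment_length=int(f[3]),
                                  unit=unit, evalue=float(f[10])))
    return hits


def write_decisions_tsv(path: str, result: FilterResult) -> None:
    with open(path, "w") as fh:
        fh.write("id\tdecision\treason\n")
        for c in result.kept:
            fh.write(f"{c.id}\tkept\t.\n")
        for c, reason in result.removed:
            fh.write(f"{c.id}\tremoved\t{reason}\n")
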