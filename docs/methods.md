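# Methods

This note documents the models, conventions and numerical choices
behind each module, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## The masked-reference experiment

All read-pair analyses assume the masked-reference setup used to study
collapsed repeats in small bacterial genomes: every copy of the IS
element is masked (replaced by N) in the reference, and a single
consensus copy is appended as a separate reference sequence. Reads
originating from any IS copy then map uniquely to the consensus. Two
consequences carry the entire analysis:

1. **Copy number.** The consensus collects the reads of all copies, so
   `mean depth(consensus) / mean depth(unique sequence)` estimates the
   copy count. The same logic applied to a duplicated cassette with one
   copy masked yields a ratio of ~2.
2. **Structural evidence.** A read pair straddling an IS junction has
   one mate on the genome and one on the consensus; per the SAM
   convention, TLEN = 0 for such cross-reference pairs. A pair flanking
   a reference-annotated element that the sample genome lacks maps with
   an insert inflated by roughly the element length (~1.5 kb), giving
   the 1500 < |TLEN| < 5000 absence window (strict on both sides).

## Synthetic data (`synthdata`)

The generator emulates the *outcome* of mapping, not mapping itself:
every simulated base knows its provenance, and reads are placed where
their sequence came from. This is deliberate — the downstream evidence
rules consume mapper output fields (FLAG, POS, TLEN, MAPQ), and an
idealized renderer makes planted truth exactly recoverable.

* Genomes are circular and linearized at a fixed origin; fragments
  crossing the origin wrap, and reads crossing it are split into
  primary + supplementary records.
* All planted IS copies are identical to the consensus (the collapsed-
  repeat idealization; real copies differ by a few substitutions).
* Reads spanning a provenance boundary are split at the boundary:
  the longest segment is the primary record, the remainder becomes a
  supplementary record. This conserves per-base depth across reference
  sequences — the idealized counterpart of soft-clipped split mapping —
  and keeps the copy-number ratio unbiased at element edges. Aligned
  spans are gapless (`<n>M`); clipping semantics of real mappers are
  not modelled, which is also why depth is counted from whole aligned
  spans in `coverage`.
* Inserts are Normal(mean, sd), rounded, floored at the read length;
  the proper-pair flag requires both mates on one reference with
  |TLEN| within insert_mean ± 4·insert_sd. Defaults (2×125 bp,
  400 ± 50, 100×) describe a typical short-read resequencing design
  for a ~1.3 Mb endosymbiont genome.
* MAPQ is 60 everywhere: with all repeat copies masked, every read has
  a unique placement by construction.
* Gene alignments evolve under Jukes–Cantor (independent sites, one
  rate, uniform frequencies) on a supplied topology via dendropy;
  recombinant genes concatenate two half-genes evolved on two
  topologies. Only topology signal matters to the screens under test,
  so no rate heterogeneity, indels or base-composition effects are
  simulated.
* All randomness derives from one integer seed through
  `numpy.random.SeedSequence` spawning (stream 0: genome construction,
  stream 1: fragment sampling keyed additionally by sample name,
  stream 2: insertion planting); gene simulation uses a Python
  `random.Random(seed)` consumed sequentially across genes.

**What passing tests do not show about real data:** no sequencing
error, no mapping ambiguity between diverged repeat copies, no
coverage bias (GC, origin-of-replication), no partial or nested
elements, and flank windows do not wrap across the origin. Recovery
rates on this generator are therefore upper bounds; on real data the
support thresholds below do real work.

## Contig screening (`contigscreen`)

* The coverage cutoff is the deepest valley of a Gaussian KDE
  (Silverman bandwidth) of **log** coverage; log scale stabilizes
  mixtures of depths that differ multiplicatively. Fewer than 10
  values is a distinct "no test" outcome, not evidence of unimodality.
* Thresholds in the homology-rescue rule are strict (> 100 aa,
  > 60%; > 200 nt, > 70%), matching "longer than"/"over" phrasing.
* Redundancy (≥ 95% identity over ≥ 90% of the shorter contig against
  another contig in the set) outranks rescue; rule order per contig is
  redundancy → homology rescue → GC → taxonomy, each removal carrying
  one machine-readable reason.
* GC outliers fall outside the central 99% interval of a normal fit
  (sample mean, sd with ddof = 1); a spread below 1e-12 is flagged as
  degenerate rather than producing zero-width bounds.

## Recombination screens (`recomb`)

* Site compatibility is the four-gamete condition on binarized
  (major/minor) states of parsimony-informative columns; gaps and
  ambiguity codes are excluded per site pair. This is a simplification
  of the refined incompatibility scores used by the classic
  implementations; it keeps the statistic exactly permutation-
  invariant and vectorizable.
* **PHI**: mean incompatibility over informative-site pairs within a
  window (default 50) measured in informative-site index distance.
  Recombination makes nearby sites more compatible than distant ones,
  so p is the lower-tail permutation fraction.
* **MaxChi** scans *all* sequence pairs, not only the most divergent
  one: the most divergent pair can have an identical relationship in
  both donor topologies of a chimera, in which case its mismatch
  profile carries no breakpoint signal and the test has no power. The
  all-pairs form (the original formulation) detects the planted
  chimeras the package simulates. Sites invalid in a pair count as
  matches in that pair's profile.
* **NSS**: compatible fraction of adjacent informative-site pairs;
  upper-tail permutation p.
* All p-values use the (b+1)/(m+1) correction; the permutation default
  is 100,000 (the reference tool's setting), with smaller counts passed
  explicitly in tests for speed. Sequences are processed in sorted-id
  order so results are invariant to input label order.
* The consensus rule calls a gene recombinant iff ≥ 2 of the 3 tests
  give p < 0.05 (strict); with fewer than 2 usable tests the gene is
  untestable, not clonal.
* Topology clustering: RF distances via dendropy on unrooted
  bipartitions; k-means needs coordinates, so the RF matrix is embedded
  by classical MDS into min(10, n−1) dimensions; hierarchical (average
  linkage) and a deterministic PAM k-medoids (greedy BUILD + SWAP) work
  on distances directly. Best (method, k) = highest silhouette, ties
  broken by smaller k then method order (hierarchical, k-means,
  k-medoids). An all-zero RF matrix is reported degenerate.

## Alignment bookkeeping (`alnstats`)

* Gap-column pruning removes columns whose gap fraction strictly
  exceeds 0.5; a provenance map of surviving columns is returned.
* Parsimony-informative: ≥ 2 states each in ≥ 2 sequences; N/X/?
  are missing, not states. Informative fractions are computed on
  nucleotide columns.
* Back-translation strips one trailing stop codon, errors on internal
  stops, and names the offending sequence in length mismatches.
* Concatenation pads missing taxa with gaps and records half-open
  column ranges per gene; partition output is RAxML-style 1-based
  inclusive.

## Coverage and copy number (`coverage`)

* Intervals are 0-based half-open (BED); SAM positions convert at
  parse time. The interval complement reproduces `bedtools complement`
  semantics and is an involution on merged sets.
* Depth excludes reads with MAPQ < 1 by default and counts whole
  aligned spans (see the synthetic-data section for why this is exact
  here).
* Copy-number calls: single (ratio ≤ 1.25), duplicated (1.75–2.25),
  multi(k) with k the nearest integer above that, inconclusive in the
  1.25–1.75 gap or whenever background CV > 0.15. The 1.25/1.75 pair
  is symmetric about 1.5 and configurable; the CV gate reflects that a
  background sd of ~30% of the mean (observed in noisy libraries)
  makes a 2× ratio uninterpretable, while ~10% is typical of clean
  100× data.

## Insertion calling (`iscaller`)

* Thresholds: flank 750 bp, absence window 1500 < |TLEN| < 5000
  (strict), MAPQ ≥ 1, proper pairs discarded — the standard improper-
  pair filter set for a ~1.5 kb element.
* `min_support = 3` pairs per call: visual inspection workflows imply
  an unstated support threshold; 3 is conservative at ≥ 20× and
  configurable.
* Novel evidence clusters by genome-mate position with a
  single-linkage window defaulting to insert_mean + 2·insert_sd
  (mates of one insertion spread over about one insert length).
* Shared evidence is attributed directionally: a forward genome mate
  points at the nearest annotated element start downstream, a reverse
  mate at the nearest end upstream. Without this, elements closer than
  2×flank bleed evidence onto each other and a genuine absence call
  degrades to "conflicting".
* Annotated loci with no evidence in a sample impute the reference
  state (present) when flank depth suffices — complete IS excisions
  are rare — otherwise unknown. Novel loci impute absent under the
  same depth condition.

## Insertion dynamics on the tree (`phylodyn`)

* The model is strict single-gain/no-loss: each locus gains once on
  the stem of the MRCA of its present leaves (loci present in all
  leaves gain on the root stem; an MRCA at the root also maps to the
  root stem). Unknown states do not constrain placement. A leaf marked
  absent inside a gained clade contradicts the model and is returned
  as an explicit violation, never silently resolved into a loss.
* Trees must be rooted with branch lengths in substitutions/site;
  rates are insertions per (substitution/site) over user-named branch
  sets, and fold ratios are reported at 1 decimal place.
* Ancestral copy counts at a node count loci whose gain branch is the
  node's stem or an ancestor of it — the minimum consistent with the
  single-gain model.

## Gene content (`content`)

* Binarization drops orthogroups single-copy in every genome (they
  carry no content signal) and collapses counts to presence.
* Clustering: average-linkage agglomeration; Euclidean distance on
  binary profiles by default (the common default when only the linkage
  is specified), Jaccard available. Genomes are processed in sorted
  column order, making dendrograms invariant to input column order;
  orthogroups absent everywhere are dropped first.
* The lineage presence rule (complete genome AND ≥ 1 draft) requires
  each lineage to designate exactly one complete genome; violations
  are errors, not warnings.

## Rate arithmetic (`rates`)

"Dividing dS by the divergence time" is ambiguous about a factor of
two (each lineage accumulates substitutions for T years). Both
conventions are implemented and every output row is labelled:
per-lineage = dS/2T, per-pair = dS/T = 2 × per-lineage. Missing
divergence times yield blank cells, never zeros. Rates format in
scientific notation at 2 significant figures.

## Problem sizes

The acceptance-scale runs use a 1,365,198 bp genome with 98 planted
1.5 kb copies at 100× (~546,000 pairs, ~11 s on one CPU) for copy-
number recovery; a 150 kb genome with 10 reference copies at 50× per
strain for the seven-strain insertion-event chain; a 200 kb genome for
cassette duplication; 100 clonal 300-site genes and 20 chimeric
1000-site genes at 199 permutations for the error-rate and power
properties. Smaller sizes in unit tests exercise the same code paths.

## Known limitations

* The generator's idealizations (no error, no mapping ambiguity, no
  bias) mean recovery results bound, rather than estimate, real-data
  performance.
* PHI/MaxChi/NSS here are permutation-only and use simplified
  compatibility scoring; analytic p-values and refined incompatibility
  are out of scope, so p-values will not match the classic tools
  digit-for-digit.
* Flank windows and novel-locus clustering do not wrap across the
  circular origin.
* Breakpoint-precision localization of insertions, genotype
  likelihoods, CNV segmentation and GC-bias correction are out of
  scope.
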