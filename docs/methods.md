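# Methods

## The analysis in brief

The pipeline quantifies how 5-azacytidine (5AzC) mutagenesis in a fungal
mutation-accumulation (MA) experiment depends on chromatin state. MA lines
are propagated through repeated single-colony bottlenecks, so mutations
accumulate nearly neutrally; sequencing each line against its ancestor and
filtering stringently yields de-novo mutation sets. Rates are then expressed
per bp per day within a three-way chromatin partition — pericentromeric
regions (PR), other H3K9me3 blocks, and the H3K9me3-free remainder — and the
mutational spectrum is summarised at six-class and 96-trinucleotide-context
resolution. Two companion analyses characterise the epigenetic response
(proportional 5mC reduction; saturating H3K9me3 decay) and the functional
load of the dominant C:G→G:C transversions (nsy/syn ratio against a
random-mutagenesis null).

## Models and estimators

**Windowed methylation.** The 5mC level of a window is the pooled fraction
Σ methylated / (Σ methylated + Σ unmethylated) over the cytosine calls it
contains, both strands pooled. Windows are non-overlapping 200-bp tiles by
default (an overlapping step is available); a window with no covered
cytosine is *missing*, never 0, and missing windows are excluded from means
and fits — imputing 0 would systematically deflate methylation averages.

**Peak blocks.** Called ChIP peaks shorter than 2 kb are discarded, then
surviving peaks separated by a gap strictly below 2 kb are merged. The
operation is idempotent, so re-processing blocks is harmless.

**ChIP normalisation.** Step 1 divides window values by total signal
(library-size proxy, ×10⁶); step 2 divides by the median of windows that do
not intersect any block. The output invariant is exact: the non-peak median
equals 1.

**Treatment-response fits.** 5mC responds proportionally: ordinary least
squares of treated on untreated window levels estimates the slope *K*
(≈ 0.5 under the default generator). H3K9me3 responds asymptotically:
*y = a − b e^(−cx)* is fitted by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, a, b, c > 0). Initialisation uses
a₀ = max(y), b₀ = spread(y), c₀ = 1/mean(x), plus one start on the c→0
tangent (a line is the c→0 limit of the model, so this start guarantees the
nonlinear training R² is never materially below the linear R²), plus seeded
log-normal jittered restarts; the best residual sum of squares wins, and
non-convergence of every restart raises. Both training-data R² values are
reported for model comparison; no cross-validation is attempted because the
comparison is descriptive.

**De-novo filters.** A candidate is retained iff line depth ≥ 5, ancestor
depth ≥ 5, ≥ 5 alt reads in the line, ≤ 1 alt read in the ancestor, site
quality > 30, and alt support on both strands. Filters are applied in that
fixed order and a record failing several is tallied under the first, making
rejection tallies reproducible; a site with no queryable ancestor evidence
is rejected under its own reason. Both homozygous and mixed-support calls
are eligible (mixed calls are flagged). Visual curation of alignments is
replaced by an automated ambiguity screen that flags mutations adjacent to
homopolymer runs ≥ 6 bp; flagged records are reported, not dropped.
Multi-allelic VCF records are split into per-allele calls before filtering.

**Classification.** Six-class labels collapse strands onto the pyrimidine
reference (C:G→T:A, C:G→A:T, C:G→G:C, T:A→C:G, T:A→G:C, T:A→A:T).
96-context labels are pyrimidine-centred N[P>Q]N; purine-reference sites
are reverse-complemented first. CDS effects use the standard codon table
(id 1); minus-strand models complement the change into the sense frame;
when several models contain a site the longest CDS provides the primary
effect and all effects are kept in a secondary field. Stop-gained changes
are counted as nonsynonymous in ratios but tallied separately.

**Rates.** Per-genome/day = count / (lines × days); per-bp/day =
count / (exposure bp × line-days), where line-days is the sum of culture
days over lines. The default exposure is the annotated stratum size; A/T-
and G/C-site rates use base-composition-specific exposures counted from the
genome within each stratum — the only denominator under which a "rate at
A/T sites" is a rate. Zero-count strata report the rule-of-three one-sided
95% upper bound (3 / exposure / line-days) instead of a bare 0. Fold
changes against a zero rate are reported as undefined (NaN), matching the
untreated methyltransferase-knockout stratum with no observed mutations.

**Rank tests.** Per-line rates are compared with the Mann–Whitney U test,
midranks for ties. With both groups ≤ 8 the null distribution of U is
enumerated over all C(n+m, n) assignments (exact, matches scipy's exact
method on tie-free data); larger groups use the normal approximation with
continuity correction.

**Spectra.** Trinucleotide opportunity is counted on both strands collapsed:
every internal genome position contributes to exactly one of 32
pyrimidine-centred trinucleotides (purine-centred positions via reverse
complement). Context rates are count / (opportunity × line-days); context
group enrichment (e.g. NCG+NCT vs NCA+NCC for C→G) is the ratio of
unweighted means of member-context rates. Signature comparison uses
probability fractions against COSMIC-layout catalogs, cosine similarity
u·v/(‖u‖‖v‖), descending rank with deterministic name tie-break, and the
conventional bands (> 0.8 high, 0.7–0.8 moderate, < 0.7 low).

**nsy/syn null.** Observed ratios divide nonsynonymous (stop-gained
included) by synonymous coding mutation counts. The null redistributes a
fixed number of changes uniformly over class-eligible coding positions —
for C:G→G:C, all coding C/G sites — sampling without replacement within an
iteration so all sites are distinct, mirroring distinct observed mutations
(with-replacement is a flag; at genome scale the difference is negligible).
Uniform site choice is the minimal assumption and is exactly what the
enumeration oracle integrates: a site-by-site walk over every eligible
change, classified through the genomic-coordinate annotator rather than the
simulation's precomputed effect table, giving an independent exact
expectation the Monte Carlo must match. Mixed-class models scale observed
class counts to the target total by largest-remainder apportionment
(deterministic, sums exactly to the target).

## What the synthetic generator emulates — and what it does not

Defaults encode the study conditions: 6 treated lines × 18 days; per-stratum
rates PR 2.1 × 10⁻⁶, non-PR H3K9me3 1.4 × 10⁻⁶, non-H3K9me3 6 × 10⁻⁷
/bp/day; the treated wild-type six-class spectrum (C:G→G:C 0.562,
C:G→T:A 0.148, T:A→C:G 0.134, C:G→A:T 0.090, the remaining A/T classes
0.033 each); sequencing depth ~63×; bisulfite depth ~30×; untreated 5mC
levels 0.33 (non-PR heterochromatin), 0.08 (PR — pericentromeres are
5mC-poor despite high H3K9me3), 0.005 elsewhere, with treated = K × untreated
at K = 0.5; ChIP domain signal ~5.4 versus background ~1.0, treated
following a − b e^(−cx) with (a, b, c) = (2.22, 2.5, 0.37). Genomes are
i.i.d. bases at 50% GC with a centred PR block per chromosome nested inside
H3K9me3 domains (drawn to a 30% genome fraction, exponential lengths,
mean 20 kb) and non-overlapping, stop-free CDS bodies.

Mutation counts per line and stratum are Poisson(rate × bp × days); classes
follow the configured spectrum, and sites are drawn uniformly without
replacement from the stratum's base-matched site pool, so positions are
unique per line. Emitted variant records pass every filter by construction;
a corruption mode adds labelled records that each violate exactly one filter
(low depth, weak alt support, ancestor-shared, single-strand, low quality),
enabling exact precision/recall benchmarking. Because ancestor evidence is
shared across lines, ancestor-contaminated corruption sites are excluded
from all other sampling.

Deliberately not modelled: read alignment and mapping bias, callable-mask
heterogeneity (exposure = annotated bp), linked or clustered mutations,
indel spectra (indels get kind labels only), bisulfite conversion failure,
and sequence composition structure beyond i.i.d. bases. Passing tests
therefore demonstrate correctness of the estimators and their calibration
under the assumed sampling model, not robustness to alignment artifacts in
real sequencing data.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeded from the
  model/spec seed; identical inputs give byte-identical FASTA/BED/GFF3/VCF
  and report outputs.
- Empty spectra have total 0 and NaN fractions (flagged, never silently 0).
- A constant-y decay fit degenerates gracefully to a = const, b ≈ 0.
- An SNV at a contig edge has no trinucleotide context; it is excluded from
  context spectra and counted in an exclusion tally.
- Observed ratio with zero synonymous mutations is NaN with counts reported.
- Interval sets are normalised (sorted, overlapping and touching intervals
  merged) at construction; block merging uses a strict `gap < threshold`
  rule.

## Problem sizes

The test suite uses a 200-kb two-chromosome genome for unit-level checks
and a 5-Mb three-chromosome genome for the study-regime recovery suite
(rate recovery within 3 Poisson SE; rate ordering in ≥ 95 of 100 seeded
replicates). The acceptance script re-runs the 5-Mb recovery, an 1.2-Mb
epigenetic-track analysis, and the 1000-iteration nsy/syn null at 1152
sites. These sizes give a few hundred mutations per replicate and tight
Monte-Carlo error while keeping a full run in the tens of seconds.

## Known limitations

- The exact per-iteration nsy/syn values of the original CDS annotation are
  only reproducible with the real genome annotation and mutation catalog;
  the package documents that workflow but its desk-scale results are
  synthetic-CDS quantities validated against the enumeration oracle.
- The repeated-measures ANOVA slot for context-group enrichment is served
  by a paired per-line comparison; the exact ANOVA structure is not
  reconstructed.
- Under the standard codon table no CDS exists in which every C:G→G:C
  change is synonymous (any codon with C/G in positions 1–2 admits a
  nonsynonymous change, and no A/T-prefixed codon has a synonymous C↔G
  third-position swap); the degenerate fixture used for validation is the
  all-nonsynonymous converse, verified by enumeration.
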