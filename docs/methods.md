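# Methods

## Coordinate model and interval algebra

All coordinates are 0-based, half-open base-pair intervals; every set of
genomic positions is held in canonical form (sorted, disjoint, adjacent
intervals merged) on a fixed autosomal `GenomeLayout`, which is the universe
for complements. Canonicalization deliberately merges touching peak records:
all statistics in the package are position-set statistics, not per-record
bookkeeping. Operations are sweep-line over interval boundaries (numpy),
never per base; a per-base boolean-array reference implementation lives in
the test suite and every operation is checked against it exactly on
randomized toy genomes.

Distances: the distance from a position to an interval set is 0 for covered
positions, otherwise the gap to the nearest covered base. "Within r" is
inclusive (d ≤ r); distance-profile rings use (lo, hi] with a first ring
[0, c₁]. At chromosome ends windows are clipped, not discarded. Breakpoint
loci are deduplicated by canonicalization when windows merge.

## The stratified odds ratio

The vicinity C is the union of ±r windows (default r = 50 kb) around all
breakpoints of the retained events (both ends of every event whose two
breakpoints are autosomal). Gene strata come from dilating the merged
transcript spans (strand ignored, isoforms merged) by the gene threshold
(default 60 kb). The 2×2×2 table counts base pairs in every combination of
stratum × vicinity × coverage; its cells always sum to the autosomal genome
size (asserted on every evaluation). The per-stratum OR is the 2×2 cross
ratio with the vicinity on the first axis, so a positive log2 OR always
means coverage is overrepresented near breakpoints.

Zero cells are handled by exclusion of the whole experiment from both
strata (no Haldane–Anscombe correction): an empty cell in either stratum
would put an infinite log OR into the aggregation. Aggregation is a
one-sample two-tailed Student's t-test (df = n − 1, sample sd with the
n − 1 denominator) of the per-experiment log2 ORs — or of their per
-experiment far−near differences, i.e. a paired comparison — against zero.
No multiple-testing correction is applied; p-values are reported raw. If
all contributing values are identical and non-zero the sd is 0 and the
summary is flagged degenerate instead of reporting an infinite t. An
alternate preset (vicinity 200 kb, gene threshold 10 kb) probes robustness
to the distance cut-offs.

Experiments are treated as independent replicates in the t-test even when
they share a cell line; this is the analysis convention the statistic is
defined with, and the synthetic generator produces genuinely independent
experiments, so calibration tests are exact for the generator and only
approximate for correlated real panels.

## Synergy

Within one cell line × lab group, each protein's experiments are unioned
into one coverage set; the genome is partitioned into classes B_k of
positions covered by exactly k proteins (sweep-line over all boundaries).
The 2-vs-1 statistic is the cross odds ratio of B₂ against B₁ with respect
to vicinity membership; k_hi/k_lo are configurable. The per-k profile uses
the complement of B_k as the reference class (a documented choice; B₀ would
be an alternative) and flags undefined entries. Groups with any zero
constituent count are excluded from aggregation, mirroring the zero-cell
filter.

## Chromatin state

State histograms score every breakpoint end against the segmentation;
uncovered ends (segmentation gaps) are excluded with a logged count.
Expected frequencies are the genome composition of the segmentation itself
(state bases / covered bases); error bars are binomial, sqrt(p̂(1−p̂)/n).
The pair matrix is over unordered end-state pairs of events with both ends
scored; the independence null uses the marginal state frequencies of those
same ends (expected{a,b} = 2·m_a·m_b off-diagonal, m_a² on the diagonal),
i.e. the expectation under random re-pairing of ends, not genome
composition. Differences are reported on the frequency scale (observed
0.30 vs expected 0.20 → +0.10) and sum to zero by construction.

## Synthetic generator

The generator emulates the structure of the real inputs — breakpoint-pair
callsets, peak experiments, block segmentations — at a scale where exact
and stochastic checks run in seconds, and injects each effect at the level
at which the pipeline estimates it:

* **Scale.** Default genome 10 Mb over 3 chromosomes, 100 genes of mean
  10 kb, 250 events (500 breakpoints), 2000 peaks of 500 bp per experiment.
  The analysis radii shrink accordingly: vicinity radius 2 kb and gene
  threshold 5 kb keep the vicinity and the near-gene stratum at ≈ 20% of
  the genome each — workable analogues of the genome-wide fractions the
  full-scale radii produce on a 3 Gb genome, chosen once as the package's
  study conditions.
* **Breakpoints.** Positions are drawn from a piecewise-constant density
  over distance-to-gene rings with weight β^(1−i/m) in ring i and 1
  outside. The default single ring at the gene threshold is the two-level
  model (weight β near genes): β > 1 genophilic, β < 1 genophobic.
  Interchromosomal events draw both ends independently on distinct
  chromosomes; intrachromosomal second ends fall at an exponential distance
  (mean 50 kb) from the first.
* **Peaks.** Per-base coverage probabilities are solved so that the
  coverage *odds* are 2^θ-fold higher inside the vicinity than outside,
  under the total budget count × length (monotone 1-D root find).  Peaks
  follow a Boolean model: starts are Poisson with intensity
  μ = −ln(1−p)/L per base and wrap around inside each placement region, so
  the realized per-base coverage probability equals p exactly (regions
  shorter than one peak saturate) and the injected OR is recovered without
  edge or overlap bias. θ may be split into θ_near/θ_far, and a
  gene-affinity term adds decaying log2-odds over distance-to-gene rings.
* **Genophilic/genophobic scenario.** The qualitative signature — the sign
  of the near-gene log2 OR flips with β while Δ = far − near stays
  positive — requires coverage and breakpoint density to *vary within* the
  near stratum; a flat two-level model cannot produce it because the
  stratification exactly controls for a constant within-stratum offset.
  The scenario therefore uses rings at 2.5/5/10 kb with gene-affinity
  amplitude 2.0 (decay 0.4) and vicinity coupling only far from genes
  (θ_near = 0, θ_far = 1.2). With β = 3 the vicinity occupies the
  gene-proximal, high-coverage part of the near stratum (near OR > 1);
  with β = 1/3 it occupies the outer fringe (near OR < 1); Δ > 0 in both.
  These values were fixed analytically from the mechanism above.
* **Segmentation.** Geometric block lengths (default mean 20 kb), states
  drawn by weight from a 15-label catalog, same-state neighbours merged;
  blocks tile each chromosome exactly.
* **Synergy groups.** Single-protein sites and shared two-protein sites are
  planted with configurable vicinity rate ratios; the planted gap is the
  log2 ratio of the two (rate and odds ratios coincide at the low coverage
  fractions used). Accidental overlap of single-protein sites from
  different proteins contaminates B₂ slightly (a few percent at default
  coverage), a small conservative bias.
* **Determinism.** One integer seed; independent child streams per section
  (genes, callset, segmentation, per-experiment peaks, per-group synergy)
  with fixed spawn keys, so adding experiments never perturbs earlier
  stages.

What the generator does *not* emulate: sequence content, realistic peak
width/score distributions, replication timing or GC covariates, chromoplexy
chain topology, and correlations between experiments sharing a cell line.
Passing tests therefore validate the statistical machinery and its
calibration, not biological conclusions about real callsets.

## Numerical and degenerate-input choices

* OR slices return NaN (a tagged "undefined" result, not an exception) when
  a denominator cell is empty; callers apply the zero-cell filter.
* Aggregation requires n ≥ 2 and raises a typed insufficient-data error
  otherwise; pipelines log and skip.
* Empty feature sets make distance partitioning undefined (error), as does
  building a vicinity from an empty callset or strata from an empty
  annotation.
* File conventions: BED-family inputs 0-based half-open; GTF 1-based
  inclusive converted on read; breakpoint tables 1-based in files, 0-based
  in memory. Autosome filtering (default chr1–chr22, configurable) happens
  at load time and never alters retained coordinates.
* Output tables are TSV with 6-significant-digit floats and documented sort
  keys; identical inputs give byte-identical outputs.

## Test problem sizes

Oracle-parity sweeps use ≥ 500 random genomes of ≤ 100 kb over ≤ 3
chromosomes. Calibration and recovery tests use the default 10 Mb study:
100 experiments for the null mean, 200 replicate aggregations of 5
experiments for the rejection rate, 8–12 experiments for recovery and the
gene-bias signature, and 6 groups for synergy recovery. The whole suite
runs in well under a minute of compute for the statistical parts.
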