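# smenrich

Stratified enrichment of protein binding, open chromatin and chromatin state
around structural-mutation (SM) breakpoints.

Somatic structural mutations — deletions, duplications, inversions,
translocations — are defined by pairs of breakpoint loci. A recurring
question in cancer genomics is whether those breakpoints preferentially
arise where proteins are bound to DNA or where chromatin is open, and
whether that association is a by-product of the well-known clustering of
breakpoints in gene regions or an independent signal. `smenrich` implements
the full analysis pipeline for that question on top of an exact
interval-set algebra over the autosomal genome, plus a synthetic-data
generator that makes every stage verifiable without any external downloads.

## The statistic

For a callset of SM events, the *vicinity* C is the set of autosomal
positions within a radius (default 50 kb) of the nearest breakpoint. The
genome is further split into *near genes* / *far from genes* strata at a
distance threshold (default 60 kb) from merged transcript spans (interior
distance is zero), and by membership in the peak coverage set H of one
ChIP-seq / DNaseI / FAIRE experiment. This yields a 2×2×2 contingency table
of base-pair counts; each gene stratum G contributes one odds ratio

    OR_G = ( |C∩H∩G| · |C*∩H*∩G| ) / ( |C∩H*∩G| · |C*∩H∩G| )

with `*` the complement. Experiments with any empty cell are excluded (the
zero-cell filter — they would give infinite log odds ratios). Per-stratum
log2 ORs and their far−near differences Δ are aggregated across experiments
with mean, sample sd and a two-tailed one-sample t-test against zero.

Companion analyses: distance-binned coverage profiles (fraction of H per
breakpoint-distance ring vs. the ring's genome-size expectation, with
per-ring ORs); multi-protein *synergy* (the genome partitioned by the exact
number k of bound proteins per cell line × lab, comparing k = 2 vs k = 1
sites); and chromatin state at breakpoints (observed-vs-genome-composition
state histograms with binomial standard errors, and unordered breakpoint-pair
state matrices against a random re-pairing null).

## Worked example

A 1 kb toy chromosome with vicinity [400,600), a near-genes stratum
[0,500) and three peaks ([100,120), [450,550), [800,820)):

```bash
python examples/enrichment_basics.py
```

```
passed zero-cell filter: True
odds ratio near genes:   19.0
odds ratio far:          19.0
log2 OR near:            4.2479
delta (far - near):      0.0
```

Each stratum sees 50 covered of 100 vicinity bases against 20 covered of
400 outside bases: OR = (50·380)/(50·20) = 19, i.e. peak coverage is
19-fold overrepresented (in odds) inside the vicinity, identically in both
strata, so Δ = 0.

Recovering an injected effect from a synthetic 10 Mb study
(`python examples/simulated_study.py`, θ = 1 injected):

```
genome: 10 Mb over 3 chromosomes
events: 250 (68 interchromosomal)
vicinity covers 18.0% of the genome
 near: n=10 mean log2 OR=+1.032 sd=0.179 p=2e-08
  far: n=10 mean log2 OR=+1.033 sd=0.080 p=1.6e-11
delta: n=10 mean log2 OR=+0.001 sd=0.223 p=0.99
```

The estimated log2 ORs recover the injected value of 1 in both strata; the
delta is null because this injection is uniform with respect to gene
proximity. The other `examples/` scripts demonstrate synergy, chromatin
states and distance profiles the same way.

## Command line

The `smenrich` executable offers `simulate`, `enrich`, `distance-profile`,
`synergy`, `states` and `run-all` subcommands over the same library; see
`smenrich --help`. `run-all` takes a YAML config and writes per-experiment
records, Table-style aggregate summaries (for all / interchromosomal-only /
intrachromosomal-only event subsets), synergy tables and chromatin-state
tables as TSV.

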