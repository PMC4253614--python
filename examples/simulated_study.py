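"""Recovering an injected enrichment from a synthetic 10 Mb study.

The generator places peak coverage with per-base coverage odds 2-fold
(θ = 1 log2 units) higher inside the breakpoint vicinity, then the analysis
estimates exactly that quantity from the realized peak sets.
"""

from smenrich import aggregate, build_vicinity, classify_gene_proximity, evaluate_peaks
from smenrich.simulate import SimConfig, simulate_callset, simulate_genome_and_genes, simulate_peaks

cfg = SimConfig(seed=7)
cfg.peaks.theta = 1.0  # injected log2 coverage odds ratio in the vicinity

layout, genes = simulate_genome_and_genes(cfg)
callset = simulate_callset(cfg, layout, genes)
vicinity = build_vicinity(callset, cfg.vicinity_radius, layout)
strata = classify_gene_proximity(genes, cfg.gene_threshold, layout)

print(f"genome: {layout.total_size / 1e6:.0f} Mb over {len(layout.names)} chromosomes")
print(f"events: {len(callset)} ({sum(e.interchromosomal for e in callset.events)} interchromosomal)")
print(f"vicinity covers {100 * vicinity.size / layout.total_size:.1f}% of the genome")

records = []
for i in range(10):
    exp = simulate_peaks(cfg, layout, vicinity, genes, index=i)
    records.append(evaluate_peaks(exp.peaks, vicinity, strata, layout))

for stratum in ("near", "far", "delta"):
    s = aggregate(records, stratum, callset="sim", assay_class="chipseq")
    print(f"{stratum:>5}: n={s.n} mean log2 OR={s.mean:+.3f} sd={s.sd:.3f} p={s.p:.2g}")
# Near and far means both sit close to the injected θ = 1; the delta is ≈ 0
# because the injection here is uniform with respect to gene proximity.
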