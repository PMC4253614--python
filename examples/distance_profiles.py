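"""How far from breakpoints does peak enrichment extend?

The genome is partitioned into distance rings around the breakpoints; each
ring gets the fraction of peak coverage it captures, the fraction expected
from its size alone, and a per-ring odds ratio.
"""

from smenrich import build_vicinity, distance_profile
from smenrich.simulate import SimConfig, simulate_callset, simulate_genome_and_genes, simulate_peaks

cfg = SimConfig(seed=5)
cfg.peaks.theta = 1.5  # strong enrichment within the 2 kb vicinity
layout, genes = simulate_genome_and_genes(cfg)
callset = simulate_callset(cfg, layout, genes)
vicinity = build_vicinity(callset, cfg.vicinity_radius, layout)
exp = simulate_peaks(cfg, layout, vicinity, genes)

profile = distance_profile(exp.peaks, callset, [2_000, 5_000, 10_000, 20_000], layout)
print(f"{'range (bp)':<16}{'observed':>10}{'expected':>10}{'OR':>8}")
for b in profile.bins:
    label = f"{b.lo}-{b.hi}" if b.hi is not None else f">{b.lo}"
    print(f"{label:<16}{b.observed_fraction:>10.3f}{b.expected_fraction:>10.3f}{b.odds_ratio:>8.2f}")
# The first ring (the injection zone) captures far more coverage than its
# size predicts (OR ≈ 2^1.5); outer rings fall back to OR ≈ or below 1.
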