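"""Multi-protein synergy: are doubly bound sites closer to breakpoints?

Each synthetic cell line × lab group plants sites bound by exactly two
proteins with a vicinity rate ratio one log2 unit above single-protein
sites; the 2-vs-1 cross odds ratio recovers that gap.
"""

from smenrich import aggregate_synergy, build_partition, build_vicinity, synergy_odds_ratio
from smenrich.simulate import SimConfig, simulate_binding_group, simulate_callset, simulate_genome_and_genes

cfg = SimConfig(seed=11)
layout, genes = simulate_genome_and_genes(cfg)
callset = simulate_callset(cfg, layout, genes)
vicinity = build_vicinity(callset, cfg.vicinity_radius, layout)

records = []
for i in range(6):
    group = simulate_binding_group(
        cfg, layout, vicinity, index=i,
        log2_rate_single=0.0, log2_rate_shared=1.0,  # planted gap: 1.0
    )
    partition = build_partition(group, layout)
    sizes = [c.size for c in partition.classes]
    rec = synergy_odds_ratio(partition, vicinity, 2, 1, cell_line=group.cell_line, lab=group.lab)
    records.append(rec)
    print(f"{group.cell_line}: |B1|={sizes[1]} bp |B2|={sizes[2]} bp log2 OR(2 vs 1)={rec.log2_or:+.3f}")

s = aggregate_synergy(records)
print(f"\nacross {s.n} groups: mean log2 OR = {s.mean:+.3f} ± {s.sd:.3f}, p = {s.p:.2g}")
# The mean recovers the planted one-log2-unit gap: doubly bound sites are
# about twice as concentrated (in odds) near breakpoints as singly bound ones.
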