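"""The 2×2×2 odds-ratio statistic on a fully worked 1 kb toy genome.

A single chromosome is split by three binary criteria — breakpoint vicinity,
gene proximity and peak coverage — and each gene stratum yields one 2×2
odds-ratio slice.  Every count here can be checked by hand.
"""

from smenrich import IntervalSet, evaluate_peaks
from smenrich.enrichment import GeneProximityPartition
from smenrich.genome import GenomeLayout

layout = GenomeLayout([("chr1", 1000)])
vicinity = IntervalSet.from_pairs(layout, [("chr1", 400, 600)])
near = IntervalSet.from_pairs(layout, [("chr1", 0, 500)])
strata = GeneProximityPartition(near=near, far=near.complement(), threshold=0)
peaks = IntervalSet.from_pairs(
    layout, [("chr1", 100, 120), ("chr1", 450, 550), ("chr1", 800, 820)]
)

rec = evaluate_peaks(peaks, vicinity, strata, layout)
print(f"passed zero-cell filter: {rec.passed_filter}")
print(f"odds ratio near genes:   {rec.or_near:.1f}")
print(f"odds ratio far:          {rec.or_far:.1f}")
print(f"log2 OR near:            {rec.log2_or_near:.4f}")
print(f"delta (far - near):      {rec.delta:.1f}")
# Both strata see 50 covered of 100 vicinity bases versus 20 covered of 400
# outside bases, so OR = (50·380)/(50·20) = 19: peak coverage is 19-fold
# overrepresented (in odds) inside the breakpoint vicinity.
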