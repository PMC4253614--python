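"""Multi-protein co-binding (synergy) around SM breakpoints.

Within one cell line × lab group, the ChIP-seq peaks of each protein are
unioned across its experiments, the genome is partitioned into classes
B_k of positions bound by exactly k distinct proteins, and sites bound by
k_hi proteins are compared with sites bound by k_lo proteins (default 2 vs
1) through the cross odds ratio

    OR = (|B_hi ∩ C| · |B_lo ∩ C*|) / (|B_hi ∩ C*| · |B_lo ∩ C|)

with C the breakpoint vicinity.  Log2 ORs are aggregated across all
cell line × lab groups with a one-sample t-test against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome import GenomeLayout, IntervalSet, coverage_classes
from .io import PeakExperiment
from .stats import AggregateSummary, one_sample_summary

__all__ = [
    "BindingGroup",
    "SynergyPartition",
    "SynergyRecord",
    "group_experiments",
    "build_partition",
    "synergy_odds_ratio",
    "per_k_profile",
    "aggregate_synergy",
]


@dataclass
class BindingGroup:
    """Per-protein peak unions within one cell line × lab combination."""

    cell_line: str
    lab: str
    proteins: dict[str, IntervalSet]

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)


@dataclass
class SynergyPartition:
    """Genome classes B_k by exact bound-protein count; tiles the genome."""

    classes: list[IntervalSet]  # index k = number of bound proteins

    @property
    def k_max(self) -> int:
        return len(self.classes) - 1


@dataclass
class SynergyRecord:
    cell_line: str
    lab: str
    callset: str
    k_hi: int
    k_lo: int
    passed_filter: bool
    odds_ratio: float = math.nan
    log2_or: float = math.nan


def group_experiments(
    experiments: list[PeakExperiment], layout: GenomeLayout
) -> list[BindingGroup]:
    """Union per-protein peaks within each (cell line, lab); ≥2-protein groups.

    Multiple experiments for one protein in a group (different antibodies or
    treatments) are unioned into a single coverage set.
    """
    by_group: dict[tuple[str, str], dict[str, IntervalSet]] = {}
    for exp in experiments:
        proteins = by_group.setdefault((exp.cell_line, exp.lab), {})
        if exp.target in proteins:
            proteins[exp.target] = proteins[exp.target].union(exp.peaks)
        else:
            proteins[exp.target] = exp.peaks
    return [
        BindingGroup(cell_line=cl, lab=lab, proteins=proteins)
        for (cl, lab), proteins in sorted(by_group.items())
        if len(proteins) >= 2
    ]


def build_partition(group: BindingGroup, layout: GenomeLayout) -> SynergyPartition:
    """B_k = positions covered by exactly k per-protein unions (sweep-line)."""
    if group.n_proteins == 0:
        raise ValueError("binding group has no proteins")
    sets = [group.proteins[p] for p in sorted(group.proteins)]
    return SynergyPartition(classes=coverage_classes(sets, layout))


def _cross_or(hi: IntervalSet, lo: IntervalSet, vicinity: IntervalSet) -> tuple[float, bool]:
    vic_out = vicinity.complement()
    a = hi.intersect(vicinity).size
    b = hi.intersect(vic_out).size
    c = lo.intersect(vicinity).size
    d = lo.intersect(vic_out).size
    if min(a, b, c, d) == 0:
        return math.nan, False
    return (a * d) / (b * c), True


def synergy_odds_ratio(
    partition: SynergyPartition,
    vicinity: IntervalSet,
    k_hi: int = 2,
    k_lo: int = 1,
    *,
    cell_line: str = "",
    lab: str = "",
    callset: str = "",
) -> SynergyRecord:
    """k_hi-proteins-vs-k_lo-proteins vicinity odds ratio for one group."""
    if not (k_hi > k_lo >= 1):
        raise ValueError("require k_hi > k_lo >= 1")
    rec = SynergyRecord(
        cell_line=cell_line,
        lab=lab,
        callset=callset,
        k_hi=k_hi,
        k_lo=k_lo,
        passed_filter=False,
    )
    if k_hi > partition.k_max:
        return rec  # class absent: filtered, not an error
    or_, ok = _cross_or(partition.classes[k_hi], partition.classes[k_lo], vicinity)
    if ok:
        rec.passed_filter = True
        rec.odds_ratio = or_
        rec.log2_or = math.log2(or_)
    return rec


def per_k_profile(
    partition: SynergyPartition, vicinity: IntervalSet, layout: GenomeLayout
) -> list[tuple[int, float]]:
    """Per-k enrichment of B_k in the vicinity against the rest of the genome.

    OR_k uses the complement of B_k as the reference class; undefined entries
    (empty class or empty cross term) are reported as NaN.
    """
    vic_out = vicinity.complement()
    out = []
    for k in range(1, partition.k_max + 1):
        bk = partition.classes[k]
        a = bk.intersect(vicinity).size
        b = bk.intersect(vic_out).size
        rest_in = vicinity.size - a
        rest_out = vic_out.size - b
        if min(a, b, rest_in, rest_out) == 0:
            out.append((k, math.nan))
        else:
            out.append((k, (a * rest_out) / (b * rest_in)))
    return out


def aggregate_synergy(records: list[SynergyRecord], *, callset: str = "") -> AggregateSummary:
    """t-test of per-group log2 synergy ORs against zero (n = groups)."""
    values = [r.log2_or for r in records if r.passed_filter]
    return one_sample_summary(values, callset=callset, assay_class="chipseq", stratum="synergy")
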