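"""Stratified enrichment of peak coverage around SM breakpoints.

The central statistic cross-classifies every autosomal base pair by three
binary criteria — distance to the nearest breakpoint (inside/outside the
vicinity, default radius 50 kb), distance to the nearest gene (near/far,
default threshold 60 kb with interior distance zero), and peak coverage —
into a 2×2×2 contingency table of base-pair counts.  Each gene stratum
yields one 2×2 slice and one odds ratio

    OR = (|C ∩ H| · |C* ∩ H*|) / (|C ∩ H*| · |C* ∩ H|)        (within stratum)

where C is the vicinity, H the peak coverage set and * the complement within
the stratum.  Experiments with any empty cell in the 2×2×2 table are
excluded outright (they would produce infinite log odds ratios); log2 ORs
and their far−near differences are aggregated across experiments with a
one-sample two-tailed t-test against zero.

Distance-binned profiles generalize the single vicinity cutoff: the genome
is partitioned into distance ranges from the breakpoints and each bin gets
the fraction of peak coverage it captures (vs. its genome-size expectation)
and a per-bin odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout, IntervalSet, distance_partition
from .io import GeneAnnotation, PeakExperiment, SMCallset
from .stats import AggregateSummary, one_sample_summary

__all__ = [
    "EnrichmentParams",
    "GeneProximityPartition",
    "Contingency222",
    "EnrichmentRecord",
    "DistanceProfile",
    "DistanceBin",
    "build_vicinity",
    "classify_gene_proximity",
    "contingency",
    "odds_ratio_slice",
    "zero_cell_filter",
    "evaluate_experiment",
    "evaluate_peaks",
    "aggregate",
    "distance_profile",
]

DEFAULT_CUTOFFS = (10_000, 50_000, 100_000, 200_000, 500_000)


@dataclass(frozen=True)
class EnrichmentParams:
    """Distance parameters of the stratified analysis (base pairs)."""

    vicinity_radius: int = 50_000
    gene_threshold: int = 60_000

    def __post_init__(self):
        if self.vicinity_radius <= 0 or self.gene_threshold <= 0:
            raise ValueError("radius and threshold must be positive")


#: Alternate preset checking robustness at longer breakpoint range and
#: tighter gene proximity (200 kb vicinity, 10 kb gene threshold).
LONG_RANGE_PARAMS = EnrichmentParams(vicinity_radius=200_000, gene_threshold=10_000)


@dataclass
class GeneProximityPartition:
    near: IntervalSet
    far: IntervalSet
    threshold: int


@dataclass
class Contingency222:
    """Base-pair counts indexed [gene stratum][vicinity][peak].

    Index 0 means near-genes / in-vicinity / under-peak respectively.
    """

    counts: np.ndarray  # shape (2, 2, 2), int64
    total: int

    def slice(self, stratum: str) -> tuple[int, int, int, int]:
        """(a, b, c, d) = (inV∧peak, inV∧noPeak, outV∧peak, outV∧noPeak)."""
        g = 0 if stratum == "near" else 1
        c = self.counts[g]
        return int(c[0, 0]), int(c[0, 1]), int(c[1, 0]), int(c[1, 1])


@dataclass
class EnrichmentRecord:
    """Per (experiment × callset) result: one odds ratio per gene stratum."""

    target: str
    cell_line: str
    lab: str
    assay_class: str
    callset: str
    passed_filter: bool
    or_near: float = math.nan
    or_far: float = math.nan
    log2_or_near: float = math.nan
    log2_or_far: float = math.nan
    delta: float = math.nan  # log2_or_far − log2_or_near


def build_vicinity(callset: SMCallset, radius: int, layout: GenomeLayout) -> IntervalSet:
    """Positions within ``radius`` of the nearest breakpoint of any event."""
    if len(callset) == 0:
        raise ValueError("cannot build a vicinity from an empty callset")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return callset.breakpoints(layout).expand(radius)


def classify_gene_proximity(
    genes: GeneAnnotation, threshold: int, layout: GenomeLayout
) -> GeneProximityPartition:
    """Split the genome at distance ``threshold`` from the merged gene spans."""
    if genes.is_empty:
        raise ValueError("gene annotation is empty")
    near = genes.dilate(threshold)
    return GeneProximityPartition(near=near, far=near.complement(), threshold=threshold)


def contingency(
    peaks: IntervalSet,
    vicinity: IntervalSet,
    strata: GeneProximityPartition,
    layout: GenomeLayout,
) -> Contingency222:
    counts = np.zeros((2, 2, 2), dtype=np.int64)
    vic_out = vicinity.complement()
    for g, stratum in enumerate((strata.near, strata.far)):
        for v, vic in enumerate((vicinity, vic_out)):
            gv = stratum.intersect(vic)
            covered = gv.intersect(peaks).size
            counts[g, v, 0] = covered
            counts[g, v, 1] = gv.size - covered
    table = Contingency222(counts=counts, total=layout.total_size)
    assert int(counts.sum()) == layout.total_size
    return table


def odds_ratio_slice(a: int, b: int, c: int, d: int) -> float:
    """(a·d)/(b·c) for a 2×2 slice; NaN when b·c = 0 (undefined OR)."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if b * c == 0:
        return math.nan
    return (a * d) / (b * c)


def zero_cell_filter(table: Contingency222) -> bool:
    """True iff all 8 cells are positive; failing experiments are excluded."""
    return bool((table.counts > 0).all())


def evaluate_peaks(
    peaks: IntervalSet,
    vicinity: IntervalSet,
    strata: GeneProximityPartition,
    layout: GenomeLayout,
    *,
    target: str = "",
    cell_line: str = "",
    lab: str = "",
    assay_class: str = "",
    callset_label: str = "",
) -> EnrichmentRecord:
    """Contingency + zero-cell filter + per-stratum log2 odds ratios."""
    table = contingency(peaks, vicinity, strata, layout)
    rec = EnrichmentRecord(
        target=target,
        cell_line=cell_line,
        lab=lab,
        assay_class=assay_class,
        callset=callset_label,
        passed_filter=zero_cell_filter(table),
    )
    if rec.passed_filter:
        rec.or_near = odds_ratio_slice(*table.slice("near"))
        rec.or_far = odds_ratio_slice(*table.slice("far"))
        rec.log2_or_near = math.log2(rec.or_near)
        rec.log2_or_far = math.log2(rec.or_far)
        rec.delta = rec.log2_or_far - rec.log2_or_near
    return rec


def evaluate_experiment(
    experiment: PeakExperiment,
    callset: SMCallset,
    genes: GeneAnnotation,
    layout: GenomeLayout,
    params: EnrichmentParams = EnrichmentParams(),
) -> EnrichmentRecord:
    """Full per-pair evaluation: vicinity, gene strata, table, odds ratios."""
    vicinity = build_vicinity(callset, params.vicinity_radius, layout)
    strata = classify_gene_proximity(genes, params.gene_threshold, layout)
    return evaluate_peaks(
        experiment.peaks,
        vicinity,
        strata,
        layout,
        target=experiment.target,
        cell_line=experiment.cell_line,
        lab=experiment.lab,
        assay_class=experiment.assay_class,
        callset_label=callset.label,
    )


def aggregate(
    records: list[EnrichmentRecord],
    stratum: str,
    *,
    callset: str = "",
    assay_class: str = "",
) -> AggregateSummary:
    """Mean/sd/two-tailed-t of per-experiment log2 ORs (or far−near deltas).

    Only records passing the zero-cell filter contribute; ``stratum`` is one
    of "near", "far" or "delta".
    """
    attr = {"near": "log2_or_near", "far": "log2_or_far", "delta": "delta"}[stratum]
    values = [getattr(r, attr) for r in records if r.passed_filter]
    return one_sample_summary(
        values, callset=callset, assay_class=assay_class, stratum=stratum
    )


@dataclass
class DistanceBin:
    lo: int  # exclusive lower distance bound (0 for the first bin)
    hi: int | None  # inclusive upper bound; None for the open-ended remainder
    size: int
    observed_fraction: float
    expected_fraction: float
    odds_ratio: float  # NaN when a cross term is empty


@dataclass
class DistanceProfile:
    bins: list[DistanceBin] = field(default_factory=list)


def distance_profile(
    peaks: IntervalSet,
    callset: SMCallset,
    cutoffs,
    layout: GenomeLayout,
) -> DistanceProfile:
    """Fraction of peak coverage per breakpoint-distance bin, with odds ratios.

    For each bin R: observed = |H∩R| / |H|, expected = |R| / genome size, and
    OR = (|H∩R|·|H*∩R*|) / (|H∩R*|·|H*∩R|) with * the genome complement.
    """
    if peaks.is_empty:
        raise ValueError("peak set is empty")
    breakpoints = callset.breakpoints(layout).expand(0)
    bins = distance_partition(breakpoints, list(cutoffs), layout)
    total = layout.total_size
    h_size = peaks.size
    out = DistanceProfile()
    lo = 0
    for i, region in enumerate(bins):
        hi = int(cutoffs[i]) if i < len(cutoffs) else None
        a = peaks.intersect(region).size  # |H ∩ R|
        b = h_size - a  # |H ∩ R*|
        c = region.size - a  # |H* ∩ R|
        d = total - h_size - c  # |H* ∩ R*|
        out.bins.append(
            DistanceBin(
                lo=lo,
                hi=hi,
                size=region.size,
                observed_fraction=a / h_size,
                expected_fraction=region.size / total,
                odds_ratio=odds_ratio_slice(a, b, c, d),
            )
        )
        lo = hi if hi is not None else lo
    return out
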