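"""Per-base boolean-array reference implementation.

Independent oracle for the sweep-line interval kernel: every operation is
re-expressed as elementwise numpy boolean logic on one array per chromosome.
Only usable on toy genomes (intended ≤ ~100 kb total).
"""

from __future__ import annotations

import numpy as np

from smenrich.genome import GenomeLayout, IntervalSet, PointSet


def masks_from(iset: IntervalSet) -> dict[str, np.ndarray]:
    out = {}
    for chrom, length in iset.layout:
        m = np.zeros(length, dtype=bool)
        for s, e in iset.intervals(chrom):
            m[s:e] = True
        out[chrom] = m
    return out


def to_intervalset(layout: GenomeLayout, masks: dict[str, np.ndarray]) -> IntervalSet:
    pairs = []
    for chrom, length in layout:
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in edges.reshape(-1, 2):
            pairs.append((chrom, int(s), int(e)))
    return IntervalSet.from_pairs(layout, pairs)


def union(layout, a, b):
    return {c: a[c] | b[c] for c, _ in layout}


def intersect(layout, a, b):
    return {c: a[c] & b[c] for c, _ in layout}


def complement(layout, a):
    return {c: ~a[c] for c, _ in layout}


def expand_points(layout: GenomeLayout, points: PointSet, radius: int):
    out = {}
    for chrom, length in layout:
        m = np.zeros(length, dtype=bool)
        for p in points.positions(chrom):
            m[max(0, p - radius) : min(length, p + radius + 1)] = True
        out[chrom] = m
    return out


def distance_to_features(layout: GenomeLayout, feat: dict[str, np.ndarray]):
    """Per-base distance to the nearest covered base (0 inside features)."""
    big = np.iinfo(np.int64).max // 2
    out = {}
    for chrom, length in layout:
        covered = np.flatnonzero(feat[chrom])
        pos = np.arange(length, dtype=np.int64)
        if len(covered) == 0:
            out[chrom] = np.full(length, big, dtype=np.int64)
            continue
        j = np.searchsorted(covered, pos)
        left = np.where(j > 0, pos - covered[np.clip(j - 1, 0, len(covered) - 1)], big)
        right = np.where(
            j < len(covered), covered[np.clip(j, 0, len(covered) - 1)] - pos, big
        )
        out[chrom] = np.minimum(left, right)
    return out


def distance_bins(layout: GenomeLayout, feat: dict[str, np.ndarray], cutoffs):
    dist = distance_to_features(layout, feat)
    bins = []
    lo = None
    for c in cutoffs:
        bins.append(
            {
                ch: (d <= c) if lo is None else (d > lo) & (d <= c)
                for ch, d in dist.items()
            }
        )
        lo = c
    bins.append({ch: d > lo for ch, d in dist.items()})
    return bins


def coverage_count(layout: GenomeLayout, mask_list):
    return {
        c: np.sum([m[c] for m in mask_list], axis=0).astype(np.int64)
        for c, _ in layout
    }


def size(masks) -> int:
    return int(sum(m.sum() for m in masks.values()))


def contingency(layout, near, vic, peaks) -> np.ndarray:
    """8 base-pair counts indexed by (gene stratum, vicinity, peak)."""
    counts = np.zeros((2, 2, 2), dtype=np.int64)
    for chrom, _ in layout:
        g, v, h = near[chrom], vic[chrom], peaks[chrom]
        for gi, gm in enumerate([g, ~g]):
            for vi, vm in enumerate([v, ~v]):
                for hi, hm in enumerate([h, ~h]):
                    counts[gi, vi, hi] += int((gm & vm & hm).sum())
    return counts
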