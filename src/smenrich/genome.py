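"""Exact interval-set algebra over a fixed autosomal genome.

All coordinates are 0-based, half-open ``[start, end)`` base-pair intervals.
Every set kept here is *canonical*: per chromosome the intervals are sorted,
pairwise disjoint, and adjacent intervals are merged, so an
:class:`IntervalSet` is an unambiguous representation of a set of genomic
positions.  All downstream counts (contingency cells, synergy classes,
distance bins) are cardinalities of such sets.

The algebra is closed over a :class:`GenomeLayout` — the ordered list of
autosomal chromosomes with their lengths — which acts as the universe for
complements.  Sex chromosomes and unplaced contigs are expected to be
filtered out upstream (see :mod:`smenrich.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "PointSet",
    "LayoutMismatchError",
    "coverage_classes",
    "distance_partition",
]


class LayoutMismatchError(ValueError):
    """Raised when combining sets defined on different genome layouts."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered autosomal chromosomes with lengths; the universe for set algebra."""

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        if not chroms:
            raise ValueError("layout must contain at least one chromosome")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)

    @cached_property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @cached_property
    def _lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_size(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, name: str) -> int:
        return self._lengths[name]

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chromosomes)


_EMPTY = np.empty((0, 2), dtype=np.int64)


def _canonicalize(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or adjacent half-open intervals."""
    if len(arr) == 0:
        return _EMPTY
    a = arr[np.argsort(arr[:, 0], kind="stable")]
    run_end = np.maximum.accumulate(a[:, 1])
    fresh = np.empty(len(a), dtype=bool)
    fresh[0] = True
    fresh[1:] = a[1:, 0] > run_end[:-1]  # start == prev end merges (adjacency)
    idx = np.flatnonzero(fresh)
    starts = a[idx, 0]
    ends = run_end[np.append(idx[1:] - 1, len(a) - 1)]
    return np.column_stack([starts, ends])


def _segment_counts(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Sweep-line coverage counts for a stack of canonical interval arrays.

    Returns unique breakpoint positions ``pos`` and ``counts`` where
    ``counts[i]`` is the number of arrays covering ``[pos[i], pos[i+1])``
    (coverage is 0 before ``pos[0]`` and after ``pos[-1]``).
    """
    pos = np.concatenate([a[:, 0] for a in arrays] + [a[:, 1] for a in arrays])
    n = sum(len(a) for a in arrays)
    delta = np.concatenate([np.ones(n, np.int64), -np.ones(n, np.int64)])
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    upos, first = np.unique(pos, return_index=True)
    counts = np.cumsum(np.add.reduceat(delta, first))
    return upos, counts


def _regions_where(upos: np.ndarray, counts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Intervals [upos[i], upos[i+1]) for inner segments where mask holds."""
    if len(upos) < 2:
        return _EMPTY
    sel = np.flatnonzero(mask[:-1])
    if len(sel) == 0:
        return _EMPTY
    return _canonicalize(np.column_stack([upos[sel], upos[sel + 1]]))


class IntervalSet:
    """A canonical set of genomic positions on a fixed :class:`GenomeLayout`."""

    __slots__ = ("layout", "_ivals")

    def __init__(self, layout: GenomeLayout, ivals: dict[str, np.ndarray] | None = None):
        self.layout = layout
        self._ivals: dict[str, np.ndarray] = ivals if ivals is not None else {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_pairs(
        cls, layout: GenomeLayout, pairs: Iterable[tuple[str, int, int]]
    ) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in pairs:
            if chrom not in layout:
                raise ValueError(f"chromosome {chrom!r} not in layout")
            start, end = int(start), int(end)
            if not (0 <= start < end <= layout.length(chrom)):
                raise ValueError(
                    f"interval [{start}, {end}) out of bounds on {chrom} "
                    f"(length {layout.length(chrom)})"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        ivals = {
            c: _canonicalize(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()
        }
        return cls(layout, ivals)

    @classmethod
    def empty(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(layout, {})

    @classmethod
    def whole_genome(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(
            layout,
            {n: np.array([[0, l]], dtype=np.int64) for n, l in layout},
        )

    # -- inspection ---------------------------------------------------------

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivals.get(chrom, _EMPTY)

    def to_pairs(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in self.layout.names:
            for s, e in self.intervals(chrom):
                out.append((chrom, int(s), int(e)))
        return out

    @property
    def size(self) -> int:
        """Number of covered base pairs."""
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values() if len(a))
        )

    @property
    def is_empty(self) -> bool:
        return all(len(a) == 0 for a in self._ivals.values())

    def covers(self, chrom: str, pos: int) -> bool:
        a = self.intervals(chrom)
        if len(a) == 0:
            return False
        i = int(np.searchsorted(a[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < a[i, 1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.layout != other.layout:
            return False
        for chrom in self.layout.names:
            if not np.array_equal(self.intervals(chrom), other.intervals(chrom)):
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n = sum(len(a) for a in self._ivals.values())
        return f"IntervalSet({n} intervals, {self.size} bp)"

    # -- algebra ------------------------------------------------------------

    def _check(self, other: "IntervalSet") -> None:
        if self.layout != other.layout:
            raise LayoutMismatchError("interval sets defined on different layouts")

    def union(self, other: "IntervalSet") -> "IntervalSet":
        self._check(other)
        ivals = {}
        for chrom in self.layout.names:
            a, b = self.intervals(chrom), other.intervals(chrom)
            if len(a) == 0 and len(b) == 0:
                continue
            ivals[chrom] = _canonicalize(np.concatenate([a, b]))
        return IntervalSet(self.layout, ivals)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        self._check(other)
        ivals = {}
        for chrom in self.layout.names:
            a, b = self.intervals(chrom), other.intervals(chrom)
            if len(a) == 0 or len(b) == 0:
                continue
            upos, counts = _segment_counts([a, b])
            reg = _regions_where(upos, counts, counts == 2)
            if len(reg):
                ivals[chrom] = reg
        return IntervalSet(self.layout, ivals)

    def complement(self) -> "IntervalSet":
        ivals = {}
        for chrom, length in self.layout:
            a = self.intervals(chrom)
            if len(a) == 0:
                ivals[chrom] = np.array([[0, length]], dtype=np.int64)
                continue
            bounds = np.concatenate([[0], a.ravel(), [length]]).reshape(-1, 2)
            keep = bounds[:, 0] < bounds[:, 1]
            if keep.any():
                ivals[chrom] = bounds[keep]
        return IntervalSet(self.layout, ivals)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        return self.intersect(other.complement())

    __or__ = union
    __and__ = intersect
    __sub__ = difference

    def dilate(self, radius: int) -> "IntervalSet":
        """Grow every interval by ``radius`` bases on both sides (clipped).

        The result covers exactly the positions at distance ≤ ``radius`` from
        a covered base, where interior positions have distance 0.
        """
        if radius < 0:
            raise ValueError("radius must be non-negative")
        ivals = {}
        for chrom, length in self.layout:
            a = self.intervals(chrom)
            if len(a) == 0:
                continue
            grown = np.column_stack(
                [np.maximum(a[:, 0] - radius, 0), np.minimum(a[:, 1] + radius, length)]
            )
            ivals[chrom] = _canonicalize(grown)
        return IntervalSet(self.layout, ivals)


class PointSet:
    """A multiset-free set of genomic positions (0-based single bases)."""

    __slots__ = ("layout", "_pos")

    def __init__(self, layout: GenomeLayout, pos: dict[str, np.ndarray]):
        self.layout = layout
        self._pos = pos

    @classmethod
    def from_pairs(
        cls, layout: GenomeLayout, pairs: Iterable[tuple[str, int]]
    ) -> "PointSet":
        by_chrom: dict[str, list[int]] = {}
        for chrom, p in pairs:
            if chrom not in layout:
                raise ValueError(f"chromosome {chrom!r} not in layout")
            p = int(p)
            if not (0 <= p < layout.length(chrom)):
                raise ValueError(f"position {p} out of bounds on {chrom}")
            by_chrom.setdefault(chrom, []).append(p)
        pos = {
            c: np.unique(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()
        }
        return cls(layout, pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def count(self) -> int:
        """Number of distinct loci."""
        return int(sum(len(v) for v in self._pos.values()))

    def expand(self, radius: int) -> IntervalSet:
        """All positions within ``radius`` bases of a point (inclusive)."""
        if radius < 0:
            raise ValueError("radius must be non-negative")
        ivals = {}
        for chrom, length in self.layout:
            p = self.positions(chrom)
            if len(p) == 0:
                continue
            arr = np.column_stack(
                [np.maximum(p - radius, 0), np.minimum(p + radius + 1, length)]
            )
            ivals[chrom] = _canonicalize(arr)
        return IntervalSet(self.layout, ivals)


def expand_points(points: PointSet, radius: int, layout: GenomeLayout) -> IntervalSet:
    """Functional alias for :meth:`PointSet.expand` (layout checked)."""
    if points.layout != layout:
        raise LayoutMismatchError("points defined on a different layout")
    return points.expand(radius)


def coverage_classes(
    sets: Sequence[IntervalSet], layout: GenomeLayout
) -> list[IntervalSet]:
    """Partition the genome by how many of ``sets`` cover each position.

    Returns ``[B_0, B_1, ..., B_K]`` (K = ``len(sets)``) where ``B_k`` is the
    set of positions covered by exactly ``k`` of the inputs.  Computed by a
    sweep over interval boundaries, never per base.
    """
    if len(sets) == 0:
        raise ValueError("need at least one interval set")
    for s in sets:
        if s.layout != layout:
            raise LayoutMismatchError("set defined on a different layout")
    k_max = len(sets)
    per_class: list[dict[str, np.ndarray]] = [dict() for _ in range(k_max + 1)]
    for chrom, length in layout:
        arrays = [s.intervals(chrom) for s in sets]
        arrays = [a for a in arrays if len(a)]
        if not arrays:
            per_class[0][chrom] = np.array([[0, length]], dtype=np.int64)
            continue
        upos, counts = _segment_counts(arrays)
        for k in range(1, k_max + 1):
            reg = _regions_where(upos, counts, counts == k)
            if len(reg):
                per_class[k][chrom] = reg
    classes = [IntervalSet(layout, iv) for iv in per_class]
    covered = classes[1]
    for k in range(2, k_max + 1):
        covered = covered.union(classes[k])
    classes[0] = covered.complement()
    return classes


def distance_partition(
    features: IntervalSet, cutoffs: Sequence[int], layout: GenomeLayout
) -> list[IntervalSet]:
    """Partition the genome into distance bins around ``features``.

    ``B_1`` holds positions at distance ≤ ``cutoffs[0]`` from the nearest
    covered base (interior distance is 0), ``B_i`` the positions in
    ``(cutoffs[i-2], cutoffs[i-1]]``, and the final bin the remainder.  The
    bins are pairwise disjoint and tile the whole autosomal genome.
    """
    if features.layout != layout:
        raise LayoutMismatchError("features defined on a different layout")
    if features.is_empty:
        raise ValueError("distance to an empty feature set is undefined")
    cutoffs = [int(c) for c in cutoffs]
    if any(c <= 0 for c in cutoffs) or any(
        b <= a for a, b in zip(cutoffs, cutoffs[1:])
    ):
        raise ValueError("cutoffs must be strictly increasing and positive")
    bins: list[IntervalSet] = []
    prev = None
    for c in cutoffs:
        grown = features.dilate(c)
        bins.append(grown if prev is None else grown.difference(prev))
        prev = grown
    bins.append(prev.complement())
    return bins
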