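"""Interval kernel: worked examples, canonical-form properties, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perbase
from conftest import random_intervalset, random_layout
from smenrich.genome import (
    GenomeLayout,
    IntervalSet,
    LayoutMismatchError,
    PointSet,
    coverage_classes,
    distance_partition,
    expand_points,
)


def iset(layout, *pairs):
    return IntervalSet.from_pairs(layout, pairs)


class TestLayout:
    def test_rejects_duplicates_and_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            GenomeLayout([("chr1", 100), ("chr1", 200)])
        with pytest.raises(ValueError):
            GenomeLayout([("chr1", 0)])

    def test_total_size(self, two_chrom_layout):
        assert two_chrom_layout.total_size == 1800


class TestSetAlgebra:
    def test_union_identity_with_empty(self, toy_layout):
        a = iset(toy_layout, ("chr1", 100, 200))
        assert IntervalSet.empty(toy_layout).union(a) == a

    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(100, 200), (150, 250)], [(100, 250)]),
            ([(100, 200), (200, 300)], [(100, 300)]),  # adjacency merged
            ([(100, 200), (300, 400)], [(100, 200), (300, 400)]),
        ],
    )
    def test_union_merges(self, toy_layout, pairs, expected):
        a = iset(toy_layout, ("chr1", *pairs[0]))
        b = iset(toy_layout, ("chr1", *pairs[1]))
        got = a.union(b)
        assert got.to_pairs() == [("chr1", s, e) for s, e in expected]
        # per-base oracle agreement
        oracle = perbase.to_intervalset(
            toy_layout,
            perbase.union(toy_layout, perbase.masks_from(a), perbase.masks_from(b)),
        )
        assert got == oracle

    def test_intersect_examples(self, toy_layout):
        a = iset(toy_layout, ("chr1", 100, 200))
        assert a.intersect(IntervalSet.whole_genome(toy_layout)) == a
        b = iset(toy_layout, ("chr1", 150, 250))
        assert a.intersect(b).to_pairs() == [("chr1", 150, 200)]
        assert a.intersect(iset(toy_layout, ("chr1", 300, 400))).is_empty

    def test_complement_examples(self, toy_layout):
        whole = IntervalSet.whole_genome(toy_layout)
        assert IntervalSet.empty(toy_layout).complement() == whole
        assert whole.complement().is_empty
        a = iset(toy_layout, ("chr1", 100, 200))
        assert a.complement().to_pairs() == [("chr1", 0, 100), ("chr1", 200, 1000)]
        assert a.size + a.complement().size == toy_layout.total_size
        assert a.intersect(a.complement()).is_empty

    def test_layout_mismatch_raises(self, toy_layout, two_chrom_layout):
        a = iset(toy_layout, ("chr1", 0, 10))
        b = iset(two_chrom_layout, ("chr1", 0, 10))
        with pytest.raises(LayoutMismatchError):
            a.union(b)

    def test_out_of_bounds_rejected(self, toy_layout):
        with pytest.raises(ValueError):
            iset(toy_layout, ("chr1", 500, 1500))
        with pytest.raises(ValueError):
            iset(toy_layout, ("chr1", 200, 200))


class TestExpandPoints:
    def test_examples(self, toy_layout):
        p = PointSet.from_pairs(toy_layout, [("chr1", 500)])
        assert expand_points(p, 0, toy_layout).to_pairs() == [("chr1", 500, 501)]
        assert expand_points(p, 100, toy_layout).to_pairs() == [("chr1", 400, 601)]
        near_edge = PointSet.from_pairs(toy_layout, [("chr1", 50)])
        assert expand_points(near_edge, 100, toy_layout).to_pairs() == [("chr1", 0, 151)]

    def test_negative_radius(self, toy_layout):
        p = PointSet.from_pairs(toy_layout, [("chr1", 500)])
        with pytest.raises(ValueError):
            p.expand(-1)

    def test_matches_oracle_on_random_points(self, two_chrom_layout):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = [
                ("chr1", int(rng.integers(0, 1000))) for _ in range(5)
            ] + [("chr2", int(rng.integers(0, 800))) for _ in range(3)]
            p = PointSet.from_pairs(two_chrom_layout, pts)
            r = int(rng.integers(0, 120))
            got = p.expand(r)
            oracle = perbase.to_intervalset(
                two_chrom_layout, perbase.expand_points(two_chrom_layout, p, r)
            )
            assert got == oracle


class TestDistancePartition:
    def test_worked_example(self, toy_layout):
        feat = iset(toy_layout, ("chr1", 500, 501))
        bins = distance_partition(feat, [100, 200], toy_layout)
        assert [b.size for b in bins] == [201, 200, 599]
        assert bins[0].to_pairs() == [("chr1", 400, 601)]
        assert bins[1].to_pairs() == [("chr1", 300, 400), ("chr1", 601, 701)]
        assert bins[2].to_pairs() == [("chr1", 0, 300), ("chr1", 701, 1000)]

    def test_whole_genome_features(self, toy_layout):
        bins = distance_partition(IntervalSet.whole_genome(toy_layout), [10, 20], toy_layout)
        assert bins[0] == IntervalSet.whole_genome(toy_layout)
        assert bins[1].is_empty and bins[2].is_empty

    def test_single_cutoff_equals_expand(self, toy_layout):
        p = PointSet.from_pairs(toy_layout, [("chr1", 100), ("chr1", 700)])
        bins = distance_partition(p.expand(0), [50], toy_layout)
        assert bins[0] == p.expand(50)

    def test_empty_features_rejected(self, toy_layout):
        with pytest.raises(ValueError):
            distance_partition(IntervalSet.empty(toy_layout), [10], toy_layout)

    def test_bad_cutoffs_rejected(self, toy_layout):
        feat = iset(toy_layout, ("chr1", 0, 10))
        for bad in ([0, 10], [20, 10], [5, 5]):
            with pytest.raises(ValueError):
                distance_partition(feat, bad, toy_layout)

    def test_partitions_genome_and_matches_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            layout = random_layout(rng, max_len=5_000)
            feat = random_intervalset(rng, layout, 4)
            if feat.is_empty:
                continue
            cutoffs = sorted(set(int(c) for c in rng.integers(1, 500, size=3)))
            bins = distance_partition(feat, cutoffs, layout)
            assert sum(b.size for b in bins) == layout.total_size
            for i, b1 in enumerate(bins):
                for b2 in bins[i + 1 :]:
                    assert b1.intersect(b2).is_empty
            oracle_bins = perbase.distance_bins(layout, perbase.masks_from(feat), cutoffs)
            for got, om in zip(bins, oracle_bins):
                assert got == perbase.to_intervalset(layout, om)


class TestCoverageClasses:
    def test_partitions_genome(self, toy_layout):
        sets = [
            iset(toy_layout, ("chr1", 0, 100)),
            iset(toy_layout, ("chr1", 50, 150)),
            iset(toy_layout, ("chr1", 60, 70)),
        ]
        classes = coverage_classes(sets, toy_layout)
        assert sum(c.size for c in classes) == toy_layout.total_size
        counts = perbase.coverage_count(toy_layout, [perbase.masks_from(s) for s in sets])
        for k, cls in enumerate(classes):
            assert cls == perbase.to_intervalset(
                toy_layout, {c: counts[c] == k for c, _ in toy_layout}
            )


# -- property tests ---------------------------------------------------------

interval_lists = st.lists(
    st.tuples(st.integers(0, 990), st.integers(1, 200)), min_size=0, max_size=12
)


def build(layout, raw):
    pairs = [("chr1", s, min(1000, s + l)) for s, l in raw if s < 1000]
    return IntervalSet.from_pairs(layout, pairs)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(raw=interval_lists)
def test_union_idempotent_and_canonical_fixed_point(raw):
    layout = GenomeLayout([("chr1", 1000)])
    a = build(layout, raw)
    assert a.union(a) == a
    # canonicalization is a fixed point: rebuilding from pairs changes nothing
    assert IntervalSet.from_pairs(layout, a.to_pairs()) == a


@settings(max_examples=60, derandomize=True, deadline=None)
@given(raw_a=interval_lists, raw_b=interval_lists)
def test_size_bounds_and_de_morgan(raw_a, raw_b):
    layout = GenomeLayout([("chr1", 1000)])
    a, b = build(layout, raw_a), build(layout, raw_b)
    u, i = a.union(b), a.intersect(b)
    assert u.size >= max(a.size, b.size)
    assert i.size <= min(a.size, b.size)
    assert u.size + i.size == a.size + b.size
    assert u.complement() == a.complement().intersect(b.complement())


@settings(max_examples=40, derandomize=True, deadline=None)
@given(raw=interval_lists, shift=st.integers(0, 500))
def test_shift_equivariance(raw, shift):
    layout = GenomeLayout([("chr1", 1000)])
    big = GenomeLayout([("chr1", 1000 + shift)])
    a = build(layout, raw)
    shifted = IntervalSet.from_pairs(
        big, [("chr1", s + shift, e + shift) for _, s, e in a.to_pairs()]
    )
    dil = a.dilate(25)
    dil_shifted = shifted.dilate(25)
    # compare away from the left boundary, which clipping makes asymmetric
    got = [(s, e) for _, s, e in dil_shifted.to_pairs() if s > shift]
    want = [(s + shift, e + shift) for _, s, e in dil.to_pairs() if s > 0]
    assert got == want
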