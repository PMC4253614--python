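"""The 2×2×2 statistic: worked toy, filters, aggregation, distance profiles."""

import math

import numpy as np
import pytest

import perbase
from conftest import random_intervalset, random_layout
from smenrich.enrichment import (
    Contingency222,
    aggregate,
    build_vicinity,
    classify_gene_proximity,
    contingency,
    distance_profile,
    evaluate_peaks,
    odds_ratio_slice,
    zero_cell_filter,
)
from smenrich.genome import GenomeLayout, IntervalSet
from smenrich.io import SMCallset, SMEvent
from smenrich.stats import InsufficientDataError, one_sample_summary


def iset(layout, *pairs):
    return IntervalSet.from_pairs(layout, pairs)


@pytest.fixture
def toy(toy_layout):
    """The fixed worked example: chr1:1000, vicinity [400,600), near [0,500)."""
    vicinity = iset(toy_layout, ("chr1", 400, 600))
    near = iset(toy_layout, ("chr1", 0, 500))
    from smenrich.enrichment import GeneProximityPartition

    strata = GeneProximityPartition(near=near, far=near.complement(), threshold=0)
    peaks = iset(
        toy_layout, ("chr1", 100, 120), ("chr1", 450, 550), ("chr1", 800, 820)
    )
    return toy_layout, peaks, vicinity, strata


class TestVicinity:
    def test_merged_intrachromosomal_windows(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        cs = SMCallset(
            "t", [SMEvent("e0", "chr1", 300_000, "chr1", 360_000)]
        )  # breakpoints 60 kb apart, radius 50 kb -> one merged interval
        vic = build_vicinity(cs, 50_000, layout)
        assert vic.to_pairs() == [("chr1", 250_000, 410_001)]
        assert vic.size == 160_001

    def test_interchromosomal_windows(self):
        layout = GenomeLayout([("chr1", 1_000_000), ("chr2", 1_000_000)])
        cs = SMCallset("t", [SMEvent("e0", "chr1", 500_000, "chr2", 500_000)])
        vic = build_vicinity(cs, 50_000, layout)
        assert [p[2] - p[1] for p in vic.to_pairs()] == [100_001, 100_001]

    def test_radius_zero_invalid_but_expand_zero_gives_loci(self, toy_layout):
        cs = SMCallset("t", [SMEvent("e0", "chr1", 100, "chr1", 100)])
        assert cs.breakpoints(toy_layout).expand(0).size == 1  # deduplicated
        with pytest.raises(ValueError):
            build_vicinity(cs, 0, toy_layout)

    def test_empty_callset_rejected(self, toy_layout):
        with pytest.raises(ValueError):
            build_vicinity(SMCallset("t", []), 50, toy_layout)


class TestGeneProximity:
    def test_boundary_convention(self, toy_layout):
        genes = iset(toy_layout, ("chr1", 0, 300))
        part = classify_gene_proximity(genes, 60, toy_layout)
        assert part.near.to_pairs() == [("chr1", 0, 360)]
        assert part.far.to_pairs() == [("chr1", 360, 1000)]

    def test_threshold_zero_is_gene_spans(self, toy_layout):
        genes = iset(toy_layout, ("chr1", 100, 200))
        part = classify_gene_proximity(genes, 0, toy_layout)
        assert part.near == genes

    def test_whole_genome_genes(self, toy_layout):
        part = classify_gene_proximity(IntervalSet.whole_genome(toy_layout), 10, toy_layout)
        assert part.far.is_empty

    def test_empty_annotation_rejected(self, toy_layout):
        with pytest.raises(ValueError):
            classify_gene_proximity(IntervalSet.empty(toy_layout), 60, toy_layout)


class TestContingency:
    def test_worked_toy_counts(self, toy):
        layout, peaks, vicinity, strata = toy
        table = contingency(peaks, vicinity, strata, layout)
        assert table.slice("near") == (50, 50, 20, 380)
        assert table.slice("far") == (50, 50, 20, 380)
        assert table.counts.sum() == layout.total_size

    def test_empty_peaks_zero_cells(self, toy):
        layout, _, vicinity, strata = toy
        table = contingency(IntervalSet.empty(layout), vicinity, strata, layout)
        assert (table.counts[:, :, 0] == 0).all()

    def test_vicinity_whole_genome(self, toy):
        layout, peaks, _, strata = toy
        table = contingency(IntervalSet.whole_genome(layout), IntervalSet.whole_genome(layout), strata, layout)
        assert (table.counts[:, 1, :] == 0).all()

    def test_matches_perbase_oracle_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            layout = random_layout(rng, max_len=4000)
            peaks = random_intervalset(rng, layout, 5)
            vic = random_intervalset(rng, layout, 3)
            genes = random_intervalset(rng, layout, 2)
            if genes.is_empty:
                continue
            strata = classify_gene_proximity(genes, int(rng.integers(1, 200)), layout)
            table = contingency(peaks, vic, strata, layout)
            oracle = perbase.contingency(
                layout,
                perbase.masks_from(strata.near),
                perbase.masks_from(vic),
                perbase.masks_from(peaks),
            )
            assert np.array_equal(table.counts, oracle)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected",
        [((50, 50, 20, 380), 19.0), ((1, 1, 1, 1), 1.0)],
    )
    def test_values(self, cells, expected):
        assert odds_ratio_slice(*cells) == expected

    def test_zero_cell_undefined(self):
        assert math.isnan(odds_ratio_slice(5, 0, 3, 7))

    def test_zero_cell_filter(self, toy):
        layout, peaks, vicinity, strata = toy
        assert zero_cell_filter(contingency(peaks, vicinity, strata, layout))
        ones = Contingency222(counts=np.ones((2, 2, 2), dtype=np.int64), total=8)
        assert zero_cell_filter(ones)
        ones.counts[0, 0, 0] = 0
        assert not zero_cell_filter(ones)


class TestEvaluate:
    def test_worked_toy_record(self, toy):
        layout, peaks, vicinity, strata = toy
        rec = evaluate_peaks(peaks, vicinity, strata, layout)
        assert rec.passed_filter
        assert rec.or_near == 19.0 and rec.or_far == 19.0
        assert rec.log2_or_near == pytest.approx(4.2479, abs=1e-4)
        assert rec.delta == 0.0

    def test_peaks_confined_to_vicinity_filtered(self, toy):
        layout, _, vicinity, strata = toy
        inside = iset(layout, ("chr1", 450, 460))
        rec = evaluate_peaks(inside, vicinity, strata, layout)
        assert not rec.passed_filter and math.isnan(rec.log2_or_near)

    def test_scale_invariance(self, toy):
        layout, peaks, vicinity, strata = toy
        big = GenomeLayout([("chr1", 2000)])

        def scaled(s):
            return IntervalSet.from_pairs(
                big, [(c, 2 * a, 2 * b) for c, a, b in s.to_pairs()]
            )

        from smenrich.enrichment import GeneProximityPartition

        strata2 = GeneProximityPartition(
            near=scaled(strata.near), far=scaled(strata.far), threshold=0
        )
        rec1 = evaluate_peaks(peaks, vicinity, strata, layout)
        rec2 = evaluate_peaks(scaled(peaks), scaled(vicinity), strata2, big)
        assert rec2.or_near == rec1.or_near and rec2.or_far == rec1.or_far


class TestAggregate:
    def test_symmetric_values(self):
        s = one_sample_summary([-1.0, 1.0])
        assert s.mean == 0.0 and s.t == 0.0 and s.p == 1.0

    def test_t_oracle_example(self):
        s = one_sample_summary([0.5, 1.0, 1.5])
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(0.5)
        assert s.t == pytest.approx(3.4641, abs=1e-4)
        assert s.p == pytest.approx(0.07418, abs=1e-5)

    def test_degenerate_sd_flagged(self):
        s = one_sample_summary([1.0, 1.0, 1.0])
        assert s.degenerate and math.isnan(s.p)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            one_sample_summary([0.5])

    def test_aggregate_uses_only_passing_records(self, toy):
        layout, peaks, vicinity, strata = toy
        good = evaluate_peaks(peaks, vicinity, strata, layout)
        bad = evaluate_peaks(iset(layout, ("chr1", 450, 460)), vicinity, strata, layout)
        s = aggregate([good, good, bad], "near")
        assert s.n == 2


class TestDistanceProfile:
    def test_worked_example(self, toy_layout):
        cs = SMCallset("t", [SMEvent("e0", "chr1", 500, "chr1", 500)])
        peaks = iset(toy_layout, ("chr1", 450, 550))
        prof = distance_profile(peaks, cs, [100, 200], toy_layout)
        assert [b.observed_fraction for b in prof.bins] == [1.0, 0.0, 0.0]
        assert [b.expected_fraction for b in prof.bins] == pytest.approx(
            [0.201, 0.200, 0.599]
        )
        # bin 1 has |H ∩ R*| = 0 -> OR undefined, flagged as NaN
        assert math.isnan(prof.bins[0].odds_ratio)
        assert sum(b.observed_fraction for b in prof.bins) == pytest.approx(1.0)
        assert sum(b.expected_fraction for b in prof.bins) == pytest.approx(1.0)

    def test_uniform_peaks_degenerate(self, toy_layout):
        cs = SMCallset("t", [SMEvent("e0", "chr1", 500, "chr1", 500)])
        prof = distance_profile(IntervalSet.whole_genome(toy_layout), cs, [100], toy_layout)
        for b in prof.bins:
            assert b.observed_fraction == pytest.approx(b.expected_fraction)
            assert math.isnan(b.odds_ratio)

    def test_empty_peaks_rejected(self, toy_layout):
        cs = SMCallset("t", [SMEvent("e0", "chr1", 500, "chr1", 500)])
        with pytest.raises(ValueError):
            distance_profile(IntervalSet.empty(toy_layout), cs, [100], toy_layout)
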