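"""Interval arithmetic, callable-mask construction and the constrained shuffle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from recland.core import (
    CallableMask,
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    build_callable_mask,
    complement,
    count_overlapping,
    covered_bp,
    intervals_frame,
    merge_intervals,
    shuffle_peaks,
    window_around_center,
)

from conftest import per_base_union, random_interval_frame


class TestLayout:
    def test_rejects_bad_chromosomes(self):
        with pytest.raises(ValueError):
            GenomeLayout({"": 100})
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})
        with pytest.raises(ValueError):
            GenomeLayout({})

    def test_validation_names_offending_record(self, layout):
        df = intervals_frame([("chr1", 10, 20), ("chr1", 500, 400)])
        with pytest.raises(ValueError, match="index 1"):
            merge_intervals(df, layout)


class TestMergeComplement:
    def test_overlap_union(self, layout):
        df = intervals_frame([("chr1", 10, 20), ("chr1", 15, 30)])
        out = merge_intervals(df, layout)
        assert out.values.tolist() == [["chr1", 10, 30]]

    def test_empty(self, layout):
        assert merge_intervals(intervals_frame(), layout).empty
        comp = complement(intervals_frame(), GenomeLayout({"chr1": 100}))
        assert comp.values.tolist() == [["chr1", 0, 100]]

    def test_adjacent_intervals_merge(self, layout):
        df = intervals_frame([("chr1", 10, 20), ("chr1", 20, 30)])
        assert merge_intervals(df, layout).values.tolist() == [["chr1", 10, 30]]

    def test_full_cover_complement_is_empty(self):
        layout = GenomeLayout({"chr1": 100})
        assert complement(intervals_frame([("chr1", 0, 100)]), layout).empty

    def test_merge_matches_per_base_oracle(self, layout, rng):
        df = random_interval_frame(rng, layout, 1000)
        merged = merge_intervals(df, layout)
        cover = per_base_union(df, layout)
        assert covered_bp(merged) == sum(int(c.sum()) for c in cover.values())
        # merged segments reproduce the per-base union exactly
        mcover = per_base_union(merged, layout)
        for c in layout.names:
            assert np.array_equal(cover[c], mcover[c])

    def test_complement_matches_per_base_oracle(self, layout, rng):
        df = random_interval_frame(rng, layout, 300)
        comp = complement(df, layout)
        cover = per_base_union(df, layout)
        ccover = per_base_union(comp, layout)
        for c in layout.names:
            assert np.array_equal(~cover[c], ccover[c])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 990), st.integers(1, 200)), max_size=40))
    def test_double_complement_is_merge(self, spans):
        layout = GenomeLayout({"chr1": 1200})
        df = intervals_frame([("chr1", s, min(1200, s + L)) for s, L in spans])
        roundtrip = complement(complement(df, layout), layout)
        assert roundtrip.equals(merge_intervals(df, layout))


class TestWindow:
    def test_arithmetic(self, layout):
        w = window_around_center(GenomicInterval("chr1", 400, 500), 100, layout)
        assert (w.start, w.end) == (350, 550)

    def test_left_clip(self, layout):
        w = window_around_center(GenomicInterval("chr1", 0, 10), 100, layout)
        assert (w.start, w.end) == (0, 105)

    def test_halfwidth_zero_is_one_bp(self, layout):
        w = window_around_center(GenomicInterval("chr1", 400, 500), 0, layout)
        assert (w.start, w.end) == (450, 451)

    def test_even_length_center_floor(self, layout):
        assert GenomicInterval("chr1", 10, 13).center == 11


class TestCountOverlapping:
    def test_shared_base(self, layout):
        n, hit = count_overlapping(intervals_frame([("chr1", 350, 550)]),
                                   intervals_frame([("chr1", 400, 500)]))
        assert n == 1 and hit.tolist() == [True]

    def test_chromosome_mismatch(self, layout):
        n, _ = count_overlapping(intervals_frame([("chr1", 350, 550)]),
                                 intervals_frame([("chr2", 400, 500)]))
        assert n == 0

    def test_touching_is_not_overlap(self):
        n, _ = count_overlapping(intervals_frame([("chr1", 100, 200)]),
                                 intervals_frame([("chr1", 200, 300)]))
        assert n == 0

    def test_matches_bruteforce_scan(self, layout, rng):
        queries = random_interval_frame(rng, layout, 200)
        targets = random_interval_frame(rng, layout, 300)
        n, hit = count_overlapping(queries, targets)
        tc = targets["chrom"].to_numpy()
        ts = targets["start"].to_numpy()
        te = targets["end"].to_numpy()
        want = np.array([
            bool(np.any((tc == q.chrom) & (ts < q.end) & (te > q.start)))
            for q in queries.itertuples(index=False)
        ])
        assert np.array_equal(hit, want) and n == int(want.sum())


class TestCallableMask:
    def test_no_exclusions_covers_genome(self, layout):
        mask = build_callable_mask(layout, intervals_frame(), intervals_frame(), 1000)
        assert mask.total_bp == layout.total_length

    def test_fully_blacklisted_chromosome_absent(self, layout):
        bl = intervals_frame([("chr1", 0, 100_000)])
        mask = build_callable_mask(layout, bl, intervals_frame(), 1000)
        assert set(mask.segments["chrom"]) == {"chr2"}

    def test_min_zero_run_threshold(self, layout):
        runs = intervals_frame([("chr1", 1000, 1500), ("chr1", 10_000, 11_500)])
        mask = build_callable_mask(layout, intervals_frame(), runs, 1000)
        # only the 1,500 bp run is excluded; the 500 bp run stays callable
        cover = per_base_union(mask.segments, layout)["chr1"]
        assert cover[1000:1500].all()
        assert not cover[10_000:11_500].any()
        assert cover.sum() == 100_000 - 1500

    def test_mask_disjoint_from_exclusions(self, layout, rng):
        bl = random_interval_frame(rng, layout, 30, max_len=3000)
        runs = random_interval_frame(rng, layout, 30, max_len=3000)
        mask = build_callable_mask(layout, bl, runs, 1000)
        long_runs = runs[(runs["end"] - runs["start"]) > 1000]
        for excluded in (bl, long_runs):
            n, _ = count_overlapping(mask.segments, excluded)
            assert n == 0

    def test_everything_excluded_errors(self):
        layout = GenomeLayout({"chr1": 100})
        with pytest.raises(ValueError, match="empty"):
            build_callable_mask(layout, intervals_frame([("chr1", 0, 100)]),
                                intervals_frame(), 1000)


class TestShuffle:
    def _mask(self, segments):
        chroms = {c: L for c, L in (("chr1", 100_000), ("chr2", 50_000))}
        return CallableMask(layout=GenomeLayout(chroms),
                            segments=intervals_frame(segments))

    def test_feasibility_bound(self):
        mask = self._mask([("chr1", 1000, 1150)])
        peaks = PeakSet("p", intervals_frame([("chr1", 0, 100)]))
        for seed in range(200):
            out = shuffle_peaks(peaks, mask, seed).intervals
            assert 1000 <= out["start"].iloc[0] <= 1050
            assert int(out["end"].iloc[0] - out["start"].iloc[0]) == 100

    def test_conserves_count_and_length_multiset(self, layout, rng):
        mask = build_callable_mask(layout, intervals_frame(), intervals_frame(), 0)
        df = random_interval_frame(rng, layout, 150, max_len=2000)
        peaks = PeakSet("p", df)
        out = shuffle_peaks(peaks, mask, 5)
        assert out.n == peaks.n
        assert np.array_equal(np.sort(out.lengths()), np.sort(peaks.lengths()))

    def test_peak_longer_than_every_segment_errors(self):
        mask = self._mask([("chr1", 0, 500), ("chr2", 0, 300)])
        peaks = PeakSet("p", intervals_frame([("chr1", 0, 100), ("chr1", 0, 900)]))
        with pytest.raises(ValueError, match="length 900"):
            shuffle_peaks(peaks, mask, 0)

    def test_placement_uniform_within_segment(self):
        # 1-bp peak in a 1,000-bp mask: per-bin counts consistent with uniformity
        mask = self._mask([("chr1", 0, 1000)])
        peaks = PeakSet("p", intervals_frame([("chr1", 0, 1)]))
        counts = np.zeros(10, dtype=int)
        for seed in range(3000):
            s = int(shuffle_peaks(peaks, mask, seed).intervals["start"].iloc[0])
            counts[s // 100] += 1
        assert stats.chisquare(counts).pvalue > 0.001

    def test_multi_segment_weighting(self):
        # two segments, lengths 300 and 100; a 100-bp peak has 201 vs 1 placements
        mask = self._mask([("chr1", 0, 300), ("chr2", 0, 100)])
        peaks = PeakSet("p", intervals_frame([("chr1", 0, 100)]))
        hits_small = sum(
            shuffle_peaks(peaks, mask, seed).intervals["chrom"].iloc[0] == "chr2"
            for seed in range(2000)
        )
        # expected fraction 1/202 ~ 0.005
        assert hits_small / 2000 < 0.03
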