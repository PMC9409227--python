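import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_peaks, stitch_oracle
from segain.coverage import CoverageTrack, build_coverage
from segain.genomic_io import Fragment, GenomicInterval, Peak
from segain.se_calling import (
    SECallParams,
    StitchedRegion,
    call_superenhancers,
    filter_blacklist,
    quantify_regions,
    stitch_peaks,
)


def peak(chrom, start, end, name="p"):
    return Peak(GenomicInterval(chrom, start, end), name=name)


class TestBlacklist:
    def test_one_bp_overlap_removes(self):
        kept = filter_blacklist([peak("chr1", 100, 200)],
                                [GenomicInterval("chr1", 150, 160)])
        assert kept == []

    def test_abutment_keeps(self):
        p = peak("chr1", 100, 200)
        assert filter_blacklist([p], [GenomicInterval("chr1", 200, 300)]) == [p]

    def test_empty_blacklist_identity(self):
        peaks = [peak("chr1", 0, 10), peak("chr2", 5, 50)]
        assert filter_blacklist(peaks, []) == peaks


class TestStitching:
    def test_gap_below_distance_merges(self):
        regions = stitch_peaks([peak("chr1", 100, 600),
                                peak("chr1", 13_000, 13_500)])
        assert len(regions) == 1
        assert regions[0].interval == GenomicInterval("chr1", 100, 13_500)

    def test_gap_at_distance_does_not_merge(self):
        # 12,500 bp apart exactly: the boundary is exclusive
        regions = stitch_peaks([peak("chr1", 100, 600),
                                peak("chr1", 13_100, 13_600)])
        assert len(regions) == 2

    def test_overlapping_peaks_always_merge(self):
        regions = stitch_peaks([peak("chr1", 0, 100), peak("chr1", 50, 150)],
                               SECallParams(stitch_distance=0))
        assert len(regions) == 1

    def test_chromosomes_never_stitch_together(self):
        regions = stitch_peaks([peak("chr1", 0, 100), peak("chr2", 0, 100)])
        assert len(regions) == 2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 60))
    def test_matches_transitive_closure_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng, n, span=100_000, chroms=("chr1", "chr2"))
        d = int(rng.integers(0, 20_000))
        regions = stitch_peaks(peaks, SECallParams(stitch_distance=max(d, 0)))
        got = sorted((r.interval.chrom, r.interval.start, r.interval.end,
                      frozenset(id(p) for p in r.member_peaks))
                     for r in regions)
        want = [(c, s, e, frozenset(id(peaks[i]) for i in members))
                for c, s, e, members in stitch_oracle(peaks, max(d, 0))]
        assert got == want

    def test_every_peak_in_exactly_one_region_and_hulls_disjoint(self):
        rng = np.random.default_rng(5)
        peaks = random_peaks(rng, 80, span=300_000)
        regions = stitch_peaks(peaks)
        members = [p for r in regions for p in r.member_peaks]
        assert sorted(id(p) for p in members) == sorted(id(p) for p in peaks)
        ordered = sorted(r.interval for r in regions)
        for a, b in zip(ordered, ordered[1:]):
            assert not a.overlaps(b)

    def test_monotone_in_stitch_distance(self):
        rng = np.random.default_rng(6)
        peaks = random_peaks(rng, 60, span=400_000)
        counts = [len(stitch_peaks(peaks, SECallParams(stitch_distance=d)))
                  for d in (0, 1_000, 5_000, 12_500, 50_000, 500_000)]
        assert counts == sorted(counts, reverse=True)


def uniform_track(chrom_len, value=1.0, bin_size=32):
    n = chrom_len // bin_size
    return CoverageTrack(bins={"chr1": np.full(n, value)}, bin_size=bin_size)


class TestQuantify:
    def test_whole_track_region_normalises_to_1e6(self):
        track = uniform_track(32_000)
        (r,) = quantify_regions(
            [StitchedRegion(GenomicInterval("chr1", 0, 32_000), [])], track)
        assert r.tag_count == pytest.approx(1e6)

    def test_region_with_no_signal_is_zero(self):
        track = uniform_track(32_000)
        track.bins["chr2"] = np.zeros(10)
        (r,) = quantify_regions(
            [StitchedRegion(GenomicInterval("chr2", 0, 320), [])], track)
        assert r.tag_count == 0.0

    def test_half_of_uniform_track(self):
        track = uniform_track(32_000)
        (r,) = quantify_regions(
            [StitchedRegion(GenomicInterval("chr1", 0, 16_000), [])], track)
        assert r.tag_count == pytest.approx(5e5)

    def test_zero_mass_track_is_error(self):
        track = uniform_track(32_000, value=0.0)
        with pytest.raises(ValueError, match="zero-mass"):
            quantify_regions(
                [StitchedRegion(GenomicInterval("chr1", 0, 320), [])], track)


def regions_with_tags(tags):
    out = []
    for i, t in enumerate(tags):
        iv = GenomicInterval("chr1", i * 1_000, i * 1_000 + 500)
        out.append(StitchedRegion(iv, [], tag_count=float(t)))
    return out


class TestTopFraction:
    def test_top_5_percent_of_2000(self):
        rng = np.random.default_rng(0)
        tags = rng.permutation(2_000) + 1.0
        res = call_superenhancers(regions_with_tags(tags))
        assert res.se_count == 100
        assert sum(r.is_super for r in res.regions) == 100
        flagged_tags = {r.tag_count for r in res.super_enhancers}
        assert flagged_tags == set(float(t) for t in range(1_901, 2_001))

    def test_minimum_one_flagged(self):
        res = call_superenhancers(regions_with_tags(range(1, 11)))
        assert res.se_count == 1
        assert res.regions[0].tag_count == 10.0

    def test_tag_count_non_increasing_with_rank(self):
        rng = np.random.default_rng(1)
        res = call_superenhancers(regions_with_tags(rng.random(333)))
        tags = [r.tag_count for r in res.regions]
        assert tags == sorted(tags, reverse=True)
        assert [r.rank for r in res.regions] == list(range(1, 334))

    def test_tie_break_is_deterministic_and_documented(self):
        # equal tags: longer region first, then (chrom, start) ascending
        a = StitchedRegion(GenomicInterval("chr1", 0, 2_000), [], tag_count=5.0)
        b = StitchedRegion(GenomicInterval("chr1", 5_000, 6_000), [], tag_count=5.0)
        c = StitchedRegion(GenomicInterval("chr1", 3_000, 4_000), [], tag_count=5.0)
        res = call_superenhancers([b, c, a], SECallParams(top_fraction=0.05))
        assert [r.interval.start for r in res.regions] == [0, 3_000, 5_000]
        assert res.se_count == 1 and res.regions[0].interval.start == 0

    def test_all_equal_n100_flags_5(self):
        res = call_superenhancers(regions_with_tags([7.0] * 100))
        assert res.se_count == 5
        # tie-break: equal tags and lengths -> lowest starts win
        assert [r.interval.start for r in res.super_enhancers] == \
            [0, 1_000, 2_000, 3_000, 4_000]

    def test_empty_region_list_is_error(self):
        with pytest.raises(ValueError):
            call_superenhancers([])

    def test_scaling_invariance_of_ranks_and_flags(self):
        rng = np.random.default_rng(2)
        frags = [Fragment(GenomicInterval("chr1", int(s), int(s) + 75),
                          "+") for s in rng.integers(0, 50_000, size=2_000)]
        track = build_coverage(frags, chrom_sizes={"chr1": 51_200})
        peaks = random_peaks(rng, 40, span=50_000, max_len=1_000)
        stitched = stitch_peaks(peaks, SECallParams(stitch_distance=500))
        res1 = call_superenhancers(quantify_regions(stitched, track))
        track.bins["chr1"] *= 7.5
        res2 = call_superenhancers(quantify_regions(stitched, track))
        assert [(r.interval, r.rank, r.is_super) for r in res1.regions] == \
            [(r.interval, r.rank, r.is_super) for r in res2.regions]
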