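"""Region calling: thresholded runs, gap merging, span filtering, and
recovery of ground-truth segments from simulated strains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covploid import (
    CallParams,
    NoiseSpec,
    NormalizedTrack,
    call_regions,
    candidate_runs,
    filter_spans,
    make_strain,
    merge_runs,
    simulate_depth,
)
from covploid.regioncall import Run
from conftest import bare_reference

P = CallParams()


def score_track(segments, length=200_000, fill=0.0):
    """Build a NormalizedTrack from (start, end, score) pieces, 1-based."""
    arr = np.full(length, fill)
    for start, end, value in segments:
        arr[start - 1 : end] = value
    return NormalizedTrack({"c1": arr})


class TestCandidateRuns:
    def test_elevated_block_yields_triploid_run(self):
        norm = score_track([(70_001, 130_000, 0.5)])
        runs = candidate_runs(norm, P)
        assert runs == [Run("c1", 70_001, 130_000, "triploid")]

    def test_short_spike_below_min_run_dropped(self):
        norm = score_track([(100_001, 100_500, 0.6)])
        assert candidate_runs(norm, P) == []

    def test_subthreshold_block_ignored(self):
        norm = score_track([(70_001, 130_000, 0.30)])
        assert candidate_runs(norm, P) == []

    def test_threshold_is_strict(self):
        norm = score_track([(70_001, 130_000, 0.35)])
        assert candidate_runs(norm, P) == []

    def test_depressed_block_yields_haploid_run(self):
        norm = score_track([(10_001, 60_000, -0.5)])
        runs = candidate_runs(norm, P)
        assert runs == [Run("c1", 10_001, 60_000, "haploid")]

    def test_nan_breaks_runs(self):
        arr = np.full(10_000, 0.5)
        arr[4_000:4_010] = np.nan
        runs = candidate_runs(NormalizedTrack({"c1": arr}), P)
        assert [(r.start, r.end) for r in runs] == [(1, 4_000), (4_011, 10_000)]


class TestMergeRuns:
    def test_gap_under_max_merges(self):
        runs = [Run("c1", 1, 10_000, "triploid"), Run("c1", 30_001, 40_000, "triploid")]
        assert merge_runs(runs, P) == [Run("c1", 1, 40_000, "triploid")]

    def test_gap_over_max_kept_separate(self):
        runs = [Run("c1", 1, 10_000, "triploid"), Run("c1", 45_001, 55_000, "triploid")]
        assert merge_runs(runs, P) == runs

    def test_gap_strictly_less_than_max(self):
        # gap of exactly 30000 bases must NOT merge ("closer than")
        runs = [Run("c1", 1, 10_000, "triploid"), Run("c1", 40_001, 50_000, "triploid")]
        assert merge_runs(runs, P) == runs

    def test_classes_never_merge(self):
        runs = [Run("c1", 1, 10_000, "triploid"), Run("c1", 10_001, 20_000, "haploid")]
        assert merge_runs(runs, P) == runs

    def test_contigs_never_merge(self):
        runs = [Run("a", 1, 10_000, "triploid"), Run("b", 1, 10_000, "triploid")]
        assert sorted(merge_runs(runs, P), key=lambda r: r.contig) == runs

    def test_transitive_merging(self):
        runs = [
            Run("c1", 1, 5_000, "triploid"),
            Run("c1", 20_001, 25_000, "triploid"),
            Run("c1", 40_001, 45_000, "triploid"),
        ]
        assert merge_runs(runs, P) == [Run("c1", 1, 45_000, "triploid")]

    def test_class_blind_mode_fuses_and_takes_longer_class(self):
        runs = [Run("c1", 1, 30_000, "triploid"), Run("c1", 35_001, 40_000, "haploid")]
        merged = merge_runs(runs, P, merge_across_classes=True)
        assert merged == [Run("c1", 1, 40_000, "triploid")]

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(1, 500_000), st.integers(1, 40_000), st.booleans()),
            max_size=12,
        )
    )
    def test_merge_is_idempotent(self, raw):
        runs = [
            Run("c1", start, start + span - 1, "triploid" if tri else "haploid")
            for start, span, tri in raw
        ]
        once = merge_runs(runs, P)
        assert merge_runs(once, P) == once


class TestFilterSpans:
    def test_long_region_retained(self):
        regions = filter_spans([Run("c1", 1, 80_000, "triploid")], P)
        assert len(regions) == 1 and regions[0].span == 80_000

    def test_short_region_dropped(self):
        assert len(filter_spans([Run("c1", 1, 45_000, "triploid")], P)) == 0

    def test_exact_min_span_dropped(self):
        # "more than 50 kbp" is strict
        assert len(filter_spans([Run("c1", 1, 50_000, "triploid")], P)) == 0

    def test_mean_score_attached(self):
        norm = score_track([(1, 80_000, 0.5)], length=100_000)
        regions = filter_spans([Run("c1", 1, 80_000, "triploid")], P, norm)
        assert regions[0].mean_score == pytest.approx(0.5)


class TestCallRegions:
    def test_recovers_injected_segments(self, aneuploid_strain, aneuploid_depth):
        regions = call_regions(aneuploid_depth)
        truth = {(s.contig, s.start, s.end, s.copy_number) for s in aneuploid_strain.cn_segments}
        assert len(regions) == len(truth) == 2
        tol = 10_000  # half the smoothing window
        for contig, start, end, cn in sorted(truth):
            cls = "triploid" if cn == 3 else "haploid"
            match = [r for r in regions if r.contig == contig and r.cls == cls]
            assert len(match) == 1
            assert abs(match[0].start - start) <= tol
            assert abs(match[0].end - end) <= tol

    def test_region_scores_near_expected_levels(self, aneuploid_depth):
        by_cls = {r.cls: r.mean_score for r in call_regions(aneuploid_depth)}
        assert by_cls["triploid"] == pytest.approx(0.5, abs=0.05)
        assert by_cls["haploid"] == pytest.approx(-0.5, abs=0.05)

    def test_all_diploid_strain_yields_nothing(self):
        ref = bare_reference([("c1", 600_000)])
        depth = simulate_depth(make_strain(ref, [], seed=0), NoiseSpec(100, seed=1))
        assert len(call_regions(depth)) == 0

    def test_dropout_artifacts_never_called(self):
        ref = bare_reference([("c1", 600_000)])
        strain = make_strain(ref, [], n_dropouts=30, seed=2)
        depth = simulate_depth(strain, NoiseSpec(100, seed=3))
        assert len(call_regions(depth)) == 0

    def test_raising_min_span_never_adds_regions(self, aneuploid_depth):
        counts = [
            len(call_regions(aneuploid_depth, CallParams(min_span=s)))
            for s in (50_000, 100_000, 150_000, 250_000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_output_regions_disjoint_and_long(self, aneuploid_depth):
        regions = call_regions(aneuploid_depth)
        assert all(r.span > P.min_span for r in regions)
        # RegionSet construction would have raised on within-class overlap


class TestCallParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hi_threshold=-0.1),
            dict(lo_threshold=0.1),
            dict(min_run=0),
            dict(max_gap=-1),
            dict(min_span=500, min_run=1000),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CallParams(**kwargs)
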