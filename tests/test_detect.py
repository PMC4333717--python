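import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imseg import (
    CpGTrack,
    DetectionParams,
    GenomicRegion,
    IMCall,
    ScoreDelta,
    apply_filters,
    build_reference_set,
    calibrate_cutoffs,
    detect_im,
    find_im_segments,
    score_deltas,
    shuffle_counts,
)
from imseg.detect import _maximal_segments
from imseg.simulate import default_benchmark_config, simulate_counts, simulate_genome

from oracles import brute_force_maximal_segments


def _deltas(values, positions=None, gaps=None):
    positions = positions if positions is not None else list(range(len(values)))
    gaps = gaps if gaps is not None else [0.0] * len(values)
    return [ScoreDelta(p, d, g) for p, d, g in zip(positions, values, gaps)]


class TestScoreDeltas:
    def test_reward_penalty_and_silent(self, raw_scale_params):
        track = CpGTrack.from_arrays(
            "s", ["chr1"] * 3, [100, 300, 400], [5.0, 5.0, 0.0], [3.0, 0.0, 0.0]
        )
        deltas = score_deltas(track, raw_scale_params(track))
        assert deltas[0].delta == pytest.approx(3.0)  # overlap: +min
        assert deltas[1].delta == pytest.approx(-5.0)  # one-sided: -max
        assert deltas[2].delta == 0.0  # silent

    def test_gap_penalty_rate(self, raw_scale_params):
        track = CpGTrack.from_arrays(
            "s", ["chr1"] * 2, [100, 300], [1.0, 1.0], [1.0, 1.0]
        )
        deltas = score_deltas(track, raw_scale_params(track))
        assert deltas[0].gap_penalty == 0.0
        assert deltas[1].gap_penalty == pytest.approx(0.01 * 200)

    def test_gap_penalty_resets_at_chromosome_start(self, small_track, raw_scale_params):
        deltas = score_deltas(small_track, raw_scale_params(small_track))
        # 5th site is the first on chr2
        assert deltas[4].gap_penalty == 0.0

    def test_overlap_weight_scales_both_signs(self, raw_scale_params):
        track = CpGTrack.from_arrays(
            "s", ["chr1"] * 2, [0, 10], [4.0, 6.0], [2.0, 0.0]
        )
        params = raw_scale_params(track)
        params.overlap_weight = 2.5
        deltas = score_deltas(track, params)
        assert deltas[0].delta == pytest.approx(2.5 * 2.0)
        assert deltas[1].delta == pytest.approx(-2.5 * 6.0)

    def test_unnormalized_track_warns_not_errors(self):
        track = CpGTrack.from_arrays("s", ["chr1"], [0], [3.0], [1.0])
        with pytest.warns(UserWarning, match="normalization targets"):
            score_deltas(track, DetectionParams())


class TestFindImSegments:
    def test_worked_example(self):
        calls = find_im_segments(_deltas([2, 3, -1, 4, -9, 1]))
        # top segment spans CpGs 0..3: running max 8 at the 4th CpG
        assert calls[0].region.start == 0 and calls[0].region.end == 4
        assert calls[0].max_score == pytest.approx(8.0)
        assert calls[0].peak_pos == 3 and calls[0].n_cpgs == 4
        # trailing positive CpG forms its own maximal segment
        assert calls[1].max_score == pytest.approx(1.0)

    def test_all_negative_yields_no_calls(self):
        assert find_im_segments(_deltas([-1, -2, -0.5])) == []

    def test_single_positive_delta(self):
        (call,) = find_im_segments(_deltas([10.0], positions=[500]))
        assert call.max_score == 10.0
        assert (call.region.start, call.region.end) == (500, 501)
        assert call.n_cpgs == 1

    def test_unordered_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            find_im_segments(_deltas([1, 1], positions=[10, 5]))

    def test_gap_penalties_subtracted(self):
        # +5 then +5 with a gap penalty of 3 at the second: total 7, peak last
        (call,) = find_im_segments(
            _deltas([5, 5], positions=[0, 100], gaps=[0.0, 3.0])
        )
        assert call.max_score == pytest.approx(7.0)
        assert call.region.end == 101

    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False, width=32), min_size=1, max_size=50
        )
    )
    def test_matches_exhaustive_maximal_segment_oracle(self, values):
        # break exact ties deterministically by nudging with tiny noise
        rng = np.random.default_rng(abs(hash(tuple(values))) % 2**31)
        x = np.asarray(values) + rng.normal(0, 1e-6, len(values))
        got = sorted((i, j, s) for i, j, s in _maximal_segments(x))
        want = brute_force_maximal_segments(x)
        assert len(got) == len(want)
        for (i1, j1, s1), (i2, j2, s2) in zip(got, want):
            assert (i1, j1) == (i2, j2)
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_score_equals_recomputed_prefix_sum(self, benchmark_sim):
        _, _, track, params = benchmark_sim
        calls = detect_im(track, params)
        deltas = score_deltas(track, params)
        by_pos = {d.pos: d for d in deltas}
        pos_sorted = sorted(by_pos)
        for call in calls[:50]:
            span = [
                by_pos[p]
                for p in pos_sorted
                if call.region.start <= p <= call.peak_pos
            ]
            total = sum(d.delta - d.gap_penalty for d in span)
            # the first CpG of a segment still pays its entry gap penalty
            assert call.max_score == pytest.approx(total, rel=1e-9)

    def test_calls_disjoint_and_sorted(self, benchmark_sim):
        _, _, track, params = benchmark_sim
        calls = detect_im(track, params)
        for a, b in zip(calls, calls[1:]):
            if a.region.chrom == b.region.chrom:
                assert a.region.end <= b.region.start


class TestShuffle:
    def test_single_site_unchanged(self):
        track = CpGTrack.from_arrays("s", ["chr1"], [5], [2.0], [3.0])
        out = shuffle_counts(track, seed=1)
        assert out.medip[0] == 2.0 and out.mre[0] == 3.0

    def test_pair_multiset_conserved(self, benchmark_sim):
        _, _, track, _ = benchmark_sim
        out = shuffle_counts(track, seed=11)
        before = sorted(zip(track.medip, track.mre))
        after = sorted(zip(out.medip, out.mre))
        assert before == after
        assert np.array_equal(out.pos, track.pos)

    def test_same_seed_reproducible(self, small_track):
        a = shuffle_counts(small_track, seed=3)
        b = shuffle_counts(small_track, seed=3)
        assert np.array_equal(a.medip, b.medip) and np.array_equal(a.mre, b.mre)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_totals_conserved_for_any_seed(self, small_track, seed):
        out = shuffle_counts(small_track, seed=seed)
        assert out.medip.sum() == pytest.approx(small_track.medip.sum())
        assert out.mre.sum() == pytest.approx(small_track.mre.sum())


def _call(start, end, score, chrom="chr1", sample=""):
    region = GenomicRegion(chrom, start, end, score=score, state="IM", sample_id=sample)
    return IMCall(region=region, max_score=score, peak_pos=end - 1, n_cpgs=2)


class TestApplyFilters:
    def test_score_cutoff_boundary(self):
        calls = [_call(0, 150, 7.9), _call(200, 350, 8.0), _call(400, 600, 12.0)]
        kept = apply_filters(calls, min_score=8.0)
        assert [c.max_score for c in kept] == [8.0, 12.0]

    def test_length_cutoff_only_when_enforced(self):
        short_high = _call(0, 90, 12.0)
        assert apply_filters([short_high], enforce_length=False) == [short_high]
        assert apply_filters([short_high], enforce_length=True) == []

    def test_monotonic_in_min_score(self, benchmark_sim):
        _, _, track, params = benchmark_sim
        calls = detect_im(track, params)
        counts = [len(apply_filters(calls, min_score=s)) for s in np.arange(1, 21, 0.5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCalibration:
    def test_planted_track_reaches_target_fpr(self, benchmark_sim):
        _, _, track, params = benchmark_sim
        result = calibrate_cutoffs(track, params, n_shuffles=25, seed=5)
        assert not result.degenerate
        assert result.fpr_estimate < 0.01
        assert result.n_shuffles == 25 and result.seed == 5
        assert len(result.null_score_dist) == len(result.null_length_dist)

    def test_zero_shuffles_rejected(self, benchmark_sim):
        _, _, track, params = benchmark_sim
        with pytest.raises(ValueError, match="n_shuffles"):
            calibrate_cutoffs(track, params, n_shuffles=0)

    def test_no_observed_calls_rejected(self):
        # one-sided signal only: the running score never rises
        track = CpGTrack.from_arrays(
            "s",
            ["chr1"] * 4,
            [0, 50, 100, 150],
            [4.0, 5.0, 6.0, 0.0],
            [0.0, 0.0, 0.0, 2.0],
        )
        params = DetectionParams(
            medip_target=float(track.medip.sum()), mre_target=float(track.mre.sum())
        )
        with pytest.raises(ValueError, match="no IM calls"):
            calibrate_cutoffs(track, params, n_shuffles=2)

    def test_pure_noise_track_flagged_degenerate(self):
        # observed == null distribution: no cutoff can reach a 1% FPR
        rng = np.random.default_rng(0)
        n = 400
        track = CpGTrack.from_arrays(
            "noise",
            ["chr1"] * n,
            np.arange(n) * 50,
            rng.poisson(2.0, n).astype(float),
            rng.poisson(2.0, n).astype(float),
        )
        params = DetectionParams(
            medip_target=float(track.medip.sum()), mre_target=float(track.mre.sum())
        )
        with pytest.warns(UserWarning, match="most stringent"):
            result = calibrate_cutoffs(track, params, n_shuffles=10, seed=2)
        assert result.degenerate


class TestReferenceSet:
    def test_nearby_calls_merge_with_support(self):
        per_sample = {
            "a": [_call(100, 200, 9.0, sample="a")],
            "b": [_call(250, 350, 10.0, sample="b")],
        }
        (region,) = build_reference_set(per_sample)
        assert (region.start, region.end) == (100, 350)
        assert region.support == 2
        assert region.score == 10.0

    def test_single_sample_region_dropped(self):
        per_sample = {"a": [_call(100, 300, 9.0, sample="a")]}
        assert build_reference_set(per_sample) == []

    def test_distant_calls_not_merged(self):
        per_sample = {
            "a": [_call(100, 200, 9.0), _call(350, 500, 9.0)],
            "b": [_call(100, 200, 9.0), _call(350, 500, 9.0)],
        }
        regions = build_reference_set(per_sample)
        assert [(r.start, r.end) for r in regions] == [(100, 200), (350, 500)]
        assert all(r.support == 2 for r in regions)

    def test_short_merged_cluster_dropped(self):
        per_sample = {
            "a": [_call(100, 160, 9.0)],
            "b": [_call(110, 170, 9.0)],
        }
        assert build_reference_set(per_sample, min_length=100) == []

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(7)
        per_sample = {}
        for s in "abcde":
            starts = np.sort(rng.choice(np.arange(0, 50_000, 400), 30, replace=False))
            per_sample[s] = [
                _call(int(x), int(x) + int(rng.integers(120, 300)), 9.0, sample=s)
                for x in starts
            ]
        ref = build_reference_set(per_sample)
        assert ref  # non-trivial fixture
        again = build_reference_set({"ref": ref})
        assert again == ref

    def test_output_gaps_exceed_merge_gap(self):
        rng = np.random.default_rng(3)
        per_sample = {
            s: [
                _call(int(x), int(x) + 150, 9.0, sample=s)
                for x in np.sort(rng.choice(np.arange(0, 30_000, 160), 40, replace=False))
            ]
            for s in "ab"
        }
        regions = build_reference_set(per_sample, merge_gap=100)
        for a, b in zip(regions, regions[1:]):
            assert b.start - a.end > 100
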