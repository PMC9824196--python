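"""The annotation algebra: 10 ms unification, consensus, frame conversion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutsound import (
    FrameGrid,
    FrameLabels,
    IntervalTrack,
    LabelInterval,
    ValidationError,
    consensus,
    frame_labels_to_intervals,
    intervals_to_frame_labels,
    unify_intervals,
)


def track(*pairs, duration=None):
    return IntervalTrack(
        tuple(LabelInterval(a, b) for a, b in pairs), clip_duration_s=duration
    )


def spans(t):
    return [(iv.start_s, iv.end_s) for iv in t.intervals]


@st.composite
def random_tracks(draw, max_events=12, duration=5.0):
    n = draw(st.integers(0, max_events))
    edges = sorted(
        draw(
            st.lists(
                st.floats(0.0, duration - 0.001, allow_nan=False),
                min_size=2 * n,
                max_size=2 * n,
                unique=True,
            )
        )
    )
    ivs = tuple(
        LabelInterval(edges[2 * i], edges[2 * i + 1]) for i in range(n)
        if edges[2 * i + 1] > edges[2 * i]
    )
    return IntervalTrack(ivs, clip_duration_s=duration)


class TestUnify:
    def test_gap_within_10ms_merges(self):
        assert spans(unify_intervals(track((0.0, 0.050), (0.055, 0.100)))) == [(0.0, 0.100)]

    def test_gap_over_10ms_kept_independent(self):
        t = track((0.0, 0.050), (0.065, 0.100))
        assert spans(unify_intervals(t)) == [(0.0, 0.050), (0.065, 0.100)]

    def test_empty(self):
        assert spans(unify_intervals(track())) == []

    def test_transitive_merge(self):
        t = track((0.0, 0.01), (0.018, 0.03), (0.038, 0.05))
        assert spans(unify_intervals(t)) == [(0.0, 0.05)]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_tracks())
    def test_idempotent_and_gap_rule(self, t):
        once = unify_intervals(t)
        assert spans(unify_intervals(once)) == spans(once)
        # never merges across > 10 ms and never leaves a <= 10 ms gap
        for a, b in zip(once.intervals, once.intervals[1:]):
            assert b.start_s - a.end_s > 0.010

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_tracks())
    def test_never_decreases_coverage(self, t):
        covered_before = sum(iv.duration_s for iv in t.intervals)
        covered_after = sum(iv.duration_s for iv in unify_intervals(t).intervals)
        assert covered_after >= covered_before - 1e-12


def brute_force_consensus(tracks, min_raters, duration, res_s=0.001):
    """Millisecond-grid voter, written independently of the implementation."""
    n = int(round(duration / res_s))
    votes = np.zeros(n, dtype=int)
    for t in tracks:
        for iv in t.intervals:
            votes[int(round(iv.start_s / res_s)) : int(round(iv.end_s / res_s))] += 1
    mask = votes >= min_raters
    out, i = [], 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i * res_s, j * res_s))
            i = j
        else:
            i += 1
    # transitive 10 ms merge
    merged = []
    for a, b in out:
        if merged and a - merged[-1][1] <= 0.010:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


class TestConsensus:
    def test_unanimity_recovers_common_track(self):
        t = track((1.0, 2.0), (3.0, 3.5), duration=5.0)
        out = consensus([t, t, t], min_raters=2)
        for got, want in zip(spans(out), spans(t)):
            assert got == pytest.approx(want, abs=1e-3)

    def test_no_two_way_overlap_gives_empty(self):
        a = track((1.0, 2.0), duration=5.0)
        b = track((3.0, 4.0), duration=5.0)
        c = track(duration=5.0)
        assert len(consensus([a, b, c], min_raters=2)) == 0

    def test_partial_overlap(self):
        a = track((1.0, 2.0), duration=3.0)
        b = track((1.5, 2.5), duration=3.0)
        c = track((0.0, 0.1), duration=3.0)
        out = consensus([a, b, c], min_raters=2)
        assert spans(out) == [(pytest.approx(1.5, abs=1e-3), pytest.approx(2.0, abs=1e-3))]

    def test_inconsistent_durations_error(self):
        a = track((1.0, 2.0), duration=5.0)
        b = track((1.0, 2.0), duration=6.0)
        with pytest.raises(ValidationError):
            consensus([a, b], min_raters=2)

    def test_matches_brute_force_voter(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            duration = 4.0
            tracks = []
            for _r in range(3):
                n = rng.integers(0, 6)
                edges = np.sort(rng.integers(0, 4000, size=2 * n)) / 1000.0
                ivs = tuple(
                    LabelInterval(float(edges[2 * i]), float(edges[2 * i + 1]))
                    for i in range(n)
                    if edges[2 * i + 1] > edges[2 * i]
                )
                tracks.append(IntervalTrack(ivs, clip_duration_s=duration))
            got = spans(consensus(tracks, min_raters=2))
            want = brute_force_consensus(tracks, 2, duration)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g[0] == pytest.approx(w[0], abs=2e-3)
                assert g[1] == pytest.approx(w[1], abs=2e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(random_tracks(max_events=6), min_size=2, max_size=4))
    def test_adding_a_rater_is_monotone(self, tracks):
        extra = tracks[0]
        base = consensus(tracks, min_raters=2)
        grown = consensus(list(tracks) + [extra], min_raters=2)
        base_cov = sum(iv.duration_s for iv in base.intervals)
        grown_cov = sum(iv.duration_s for iv in grown.intervals)
        assert grown_cov >= base_cov - 1e-9


class TestFrameConversion:
    grid25 = FrameGrid(n_frames=20, frame_length_s=0.1, hop_s=0.025)
    grid100 = FrameGrid(n_frames=10, frame_length_s=0.1, hop_s=0.1)

    def test_interval_equal_to_frame_is_positive(self):
        labels = intervals_to_frame_labels(track((0.1, 0.2)), self.grid100)
        assert labels.values[1] == 1

    def test_empty_track_all_negative(self):
        labels = intervals_to_frame_labels(track(), self.grid25)
        assert labels.values.sum() == 0

    def test_overlap_threshold_frame_by_frame(self):
        # oracle: explicit overlap of (0.050, 0.150) with each 100 ms frame
        labels = intervals_to_frame_labels(track((0.050, 0.150)), self.grid25)
        for i in range(self.grid25.n_frames):
            lo, hi = i * 0.025, i * 0.025 + 0.1
            overlap = max(0.0, min(hi, 0.150) - max(lo, 0.050))
            assert labels.values[i] == (1 if overlap >= 0.05 - 1e-12 else 0), f"frame {i}"

    def test_all_negative_gives_empty_track(self):
        labels = FrameLabels(values=np.zeros(10, dtype=np.uint8), grid=self.grid100)
        assert len(frame_labels_to_intervals(labels)) == 0

    def test_single_positive_frame(self):
        values = np.zeros(20, dtype=np.uint8)
        values[4] = 1
        out = frame_labels_to_intervals(FrameLabels(values=values, grid=self.grid25))
        assert spans(out) == [(pytest.approx(0.1), pytest.approx(0.2))]

    def test_boundary_aligned_round_trip(self):
        # on the non-overlapping grid, intervals aligned to frame edges
        # survive intervals -> frames -> intervals exactly
        t = track((0.1, 0.3), (0.5, 0.6), duration=1.0)
        labels = intervals_to_frame_labels(t, self.grid100)
        back = frame_labels_to_intervals(labels)
        assert spans(back) == [
            (pytest.approx(0.1), pytest.approx(0.3)),
            (pytest.approx(0.5), pytest.approx(0.6)),
        ]

    def test_frames_to_intervals_to_frames_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            values = (rng.random(10) < 0.4).astype(np.uint8)
            labels = FrameLabels(values=values, grid=self.grid100)
            back = intervals_to_frame_labels(frame_labels_to_intervals(labels), self.grid100)
            assert np.array_equal(back.values, values)
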