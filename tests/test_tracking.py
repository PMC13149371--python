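import numpy as np
import pytest
from hypothesis import given, strategies as st

from deptrack.detection import Detection, detections_from_dataframe
from deptrack.simulate import corrupt_detections
from deptrack.tracking import (
    Track,
    TrackerConfig,
    TrackState,
    associate,
    circle_iou,
    interpolate_gap,
    out_of_range_filter,
    overlap_identity_check,
    recover_gap,
    track_sequence,
)


def det(x, y, r=5.0, frame=0):
    return Detection(frame=frame, x=x, y=y, r=r)


def make_track(cell_id, states):
    return Track(cell_id=cell_id, states=[TrackState(x, y, r, "detected") for x, y, r in states])


class TestCircleIoU:
    def test_identical_circles(self):
        assert circle_iou((3, 4, 7), (3, 4, 7)) == pytest.approx(1.0)

    def test_disjoint_circles(self):
        assert circle_iou((0, 0, 2), (10, 0, 2)) == 0.0
        assert circle_iou((0, 0, 2), (4, 0, 2)) == 0.0  # exactly touching

    def test_unit_circles_at_unit_distance(self):
        # closed-form lens area: 2 acos(1/2) - sqrt(3)/2 over the union
        assert circle_iou((0, 0, 1), (1, 0, 1)) == pytest.approx(0.2430, abs=5e-4)

    def test_contained_circle(self):
        assert circle_iou((0, 0, 1), (0.5, 0, 3)) == pytest.approx(1 / 9)

    @given(
        st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0.5, 10), st.floats(0.5, 10), st.floats(0, 15),
        st.floats(0, 2 * np.pi),
    )
    def test_symmetric_and_rigid_motion_invariant(self, tx, ty, r1, r2, d, ang):
        c1 = (0.0, 0.0, r1)
        c2 = (d * np.cos(ang), d * np.sin(ang), r2)
        base = circle_iou(c1, c2)
        assert circle_iou(c2, c1) == pytest.approx(base, abs=1e-12)
        moved = circle_iou((tx, ty, r1), (tx + c2[0], ty + c2[1], r2))
        assert moved == pytest.approx(base, abs=1e-9)
        assert 0.0 <= base <= 1.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            circle_iou((0, 0, 0), (1, 1, 1))


class TestAssociate:
    cfg = TrackerConfig(gates_in_radii=False, roi_stable=15, dist_stable=10,
                        iou_stable=0.3, roi_rapid=30, dist_rapid=20, iou_rapid=0.05)

    def test_nearby_detection_matched(self):
        tr = make_track(0, [(0, 0, 5)])
        assert associate(tr, [det(2, 0)], "stable", self.cfg) == 0

    def test_argmin_first_semantics(self):
        # the distance-minimizer fails the IoU gate; a farther feasible
        # candidate exists but is not examined
        tr = make_track(0, [(0, 0, 5)])
        near_bad = det(2, 0, r=0.5)   # contained tiny disc: IoU = 0.01 < 0.3
        far_good = det(4, 0, r=5.0)   # IoU ~ 0.34 >= 0.3
        assert associate(tr, [near_bad, far_good], "stable", self.cfg) is None
        best = TrackerConfig(gates_in_radii=False, roi_stable=15, dist_stable=10,
                             iou_stable=0.3, roi_rapid=30, dist_rapid=20,
                             iou_rapid=0.05, best_feasible=True)
        assert associate(tr, [near_bad, far_good], "stable", best) == 1

    def test_empty_detections(self):
        tr = make_track(0, [(0, 0, 5)])
        assert associate(tr, [], "stable", self.cfg) is None

    def test_rapid_regime_relaxes_gates(self):
        tr = make_track(0, [(0, 0, 5)])
        assert associate(tr, [det(40, 0)], "stable", self.cfg) is None
        assert associate(tr, [det(40, 0)], "rapid", self.cfg) is None
        jump = det(8, 0)  # IoU ~ 0.055: passes rapid tau, fails stable tau
        assert associate(tr, [jump], "stable", self.cfg) is None
        assert associate(tr, [jump], "rapid", self.cfg) == 0

    def test_tie_breaks_to_lower_index(self):
        tr = make_track(0, [(0, 0, 5)])
        assert associate(tr, [det(3, 0), det(-3, 0)], "stable", self.cfg) == 0

    def test_rapid_gates_must_be_relaxed(self):
        with pytest.raises(ValueError):
            TrackerConfig(roi_stable=5, roi_rapid=3)
        with pytest.raises(ValueError):
            TrackerConfig(iou_stable=0.1, iou_rapid=0.2)


class TestRecoverGap:
    cfg = TrackerConfig(gates_in_radii=False, roi_stable=15, roi_rapid=15,
                        dist_stable=15, dist_rapid=15, iou_rapid=0.05, max_gap=10)

    def test_detection_reappearing_within_window(self):
        tr = make_track(0, [(0, 0, 5)])
        by_frame = {13: [det(3, 0, frame=13)]}
        assert recover_gap(tr, by_frame, 10, self.cfg) == (13, 0)

    def test_nothing_within_max_gap(self):
        tr = make_track(0, [(0, 0, 5)])
        by_frame = {25: [det(1, 0, frame=25)]}  # beyond 10 + max_gap
        assert recover_gap(tr, by_frame, 10, self.cfg) is None

    def test_nearer_candidate_chosen_then_lower_index(self):
        tr = make_track(0, [(0, 0, 5)])
        by_frame = {12: [det(9, 0), det(-4, 0)]}
        assert recover_gap(tr, by_frame, 10, self.cfg) == (12, 1)
        by_frame = {12: [det(4, 0), det(-4, 0)]}  # exact tie
        assert recover_gap(tr, by_frame, 10, self.cfg) == (12, 0)

    def test_claimed_detections_skipped(self):
        tr = make_track(0, [(0, 0, 5)])
        by_frame = {12: [det(3, 0)]}
        assert recover_gap(tr, by_frame, 10, self.cfg, used={12: {0}}) is None


class TestInterpolateGap:
    def test_linear_positions(self):
        a = TrackState(0, 0, 5, "detected")
        b = TrackState(10, 0, 5, "detected")
        states = interpolate_gap(a, b, 10, 15)
        assert [(s.x, s.y) for s in states] == [(2, 0), (4, 0), (6, 0), (8, 0)]
        assert all(s.source == "interpolated" for s in states)

    def test_zero_length_gap(self):
        a = TrackState(0, 0, 5, "detected")
        b = TrackState(10, 0, 5, "detected")
        assert interpolate_gap(a, b, 10, 11) == []

    def test_radius_interpolated(self):
        a = TrackState(0, 0, 10, "detected")
        b = TrackState(0, 0, 12, "detected")
        (mid,) = interpolate_gap(a, b, 0, 2)
        assert mid.r == pytest.approx(11.0)


@pytest.fixture(scope="module")
def clean_stream(small_benchmark):
    exp, tracks = small_benchmark
    df = corrupt_detections(tracks, seed=5)
    return detections_from_dataframe(df)


class TestTrackSequence:
    def test_noise_free_stream_reproduces_ground_truth(self, small_benchmark, clean_stream, fov_mask):
        exp, gt = small_benchmark
        n = gt[0].n_frames
        tracks, conflicts = track_sequence(clean_stream, [], fov_mask, n_frames=n)
        assert len(tracks) == len(gt)
        assert conflicts == []
        order = np.argsort([np.hypot(*t.states[0]) for t in gt])
        for tr in tracks:
            assert tr.length == n
            assert all(s.source == "detected" for s in tr.states)
        # positions match ground truth exactly (one-to-one by start point)
        starts_pred = sorted((t.states[0].x, t.states[0].y) for t in tracks)
        starts_gt = sorted((t.states[0][0], t.states[0][1]) for t in gt)
        np.testing.assert_allclose(starts_pred, starts_gt)

    def test_dropout_bridged_by_interpolation(self):
        by_frame = {
            t: [det(10.0 + 2 * t, 50.0, frame=t)] for t in range(10)
        }
        for t in (4, 5, 6):  # 3-frame dropout
            by_frame[t] = []
        tracks, _ = track_sequence(by_frame, [], None, n_frames=10)
        (tr,) = tracks
        assert tr.length == 10
        assert [s.source for s in tr.states[4:7]] == ["interpolated"] * 3
        np.testing.assert_allclose([s.x for s in tr.states], 10 + 2 * np.arange(10))

    def test_late_entrant_gets_no_track(self):
        by_frame = {t: [det(10.0, 10.0, frame=t)] for t in range(20)}
        for t in range(5, 20):
            by_frame[t].append(det(100.0, 100.0, frame=t))
        tracks, _ = track_sequence(by_frame, [], None, n_frames=20)
        assert len(tracks) == 1
        assert tracks[0].states[0].x == 10.0

    def test_empty_first_frame_rejected(self):
        with pytest.raises(ValueError):
            track_sequence({1: [det(0, 0)]}, [], None, n_frames=5)

    def test_track_terminates_when_cell_vanishes(self):
        by_frame = {t: [det(10.0, 10.0, frame=t)] for t in range(30)}
        for t in range(12, 30):
            by_frame[t] = []
        tracks, _ = track_sequence(by_frame, [], None, n_frames=30)
        assert tracks[0].length == 12  # last state at frame 11, no extrapolation

    def test_interpolated_runs_never_exceed_max_gap(self):
        cfg = TrackerConfig(max_gap=4)
        by_frame = {t: [det(10.0, 10.0, frame=t)] for t in range(30)}
        for t in range(10, 16):  # 6-frame dropout > max_gap
            by_frame[t] = []
        tracks, _ = track_sequence(by_frame, [], None, cfg, n_frames=30)
        assert tracks[0].length == 10  # terminated, not bridged


class TestValidation:
    def test_full_length_in_mask_track_is_valid(self, fov_mask):
        c = np.array(fov_mask.mask.shape)[::-1] / 2
        tr = make_track(0, [(c[0], c[1], 5)] * 100)
        valid, out = out_of_range_filter([tr], 100, fov_mask)
        assert valid == [tr] and out == []

    def test_short_track_is_out_of_range(self, fov_mask):
        c = np.array(fov_mask.mask.shape)[::-1] / 2
        tr = make_track(0, [(c[0], c[1], 5)] * 99)
        valid, out = out_of_range_filter([tr], 100, fov_mask)
        assert valid == [] and out == [tr] and tr.status == "out_of_range"

    def test_excursion_into_border_band_is_out_of_range(self, fov_mask):
        c = np.array(fov_mask.mask.shape)[::-1] / 2
        states = [(c[0], c[1], 5)] * 100
        states[50] = (c[0], 3.0, 5)  # inside the blanked top rows
        tr = make_track(0, states)
        valid, out = out_of_range_filter([tr], 100, fov_mask)
        assert out == [tr]

    def test_conservation_identity(self, small_benchmark, fov_mask):
        # first-frame detections = valid + out-of-range tracks
        exp, gt = small_benchmark
        n = gt[0].n_frames
        df = corrupt_detections(gt, p_miss=0.05, pos_sigma=1.0, seed=17)
        stream = detections_from_dataframe(df)
        tracks, _ = track_sequence(stream, [], fov_mask, n_frames=n)
        valid, out = out_of_range_filter(tracks, n, fov_mask)
        assert len(valid) + len(out) == len(stream[0])


class TestOverlapIdentityCheck:
    def test_single_frame_crossing_is_no_event(self):
        a = make_track(0, [(t, 0.0, 5) for t in range(10)])
        b = make_track(1, [(9 - t, 0.4, 5) for t in range(10)])
        events = overlap_identity_check([a, b], tau_overlap=0.5, min_consecutive=3)
        assert events == []

    def test_swapped_tails_corrected(self):
        # two cells approach, overlap five frames, then separate; the input
        # tracks carry exchanged tails (as a greedy pass would leave them)
        left = [(-10.0 + t, 0.0) for t in range(21)]   # moves right
        right = [(10.0 - t, 0.1) for t in range(21)]   # moves left
        e = 12  # identities exchanged right as the overlap run ends
        a_states = left[:e] + right[e:]
        b_states = right[:e] + left[e:]
        a = make_track(0, [(x, y, 5) for x, y in a_states])
        b = make_track(1, [(x, y, 5) for x, y in b_states])
        events = overlap_identity_check([a, b], tau_overlap=0.5, min_consecutive=3)
        kinds = [ev["kind"] for ev in events]
        assert "swapped" in kinds
        ev = events[kinds.index("swapped")]
        assert ev["cost_after"] < ev["cost_before"]
        # tails restored: each track is straight-line again
        xs = [s.x for s in a.states]
        assert np.all(np.diff(xs) > 0) or np.all(np.diff(xs) < 0)

    def test_fully_coincident_tracks_flagged_merged(self):
        a = make_track(0, [(5.0, 5.0, 5)] * 12)
        b = make_track(1, [(5.2, 5.0, 5)] * 12)
        events = overlap_identity_check([a, b], tau_overlap=0.5, min_consecutive=3)
        assert [ev["kind"] for ev in events] == ["merged"]
        assert a.status == b.status == "merged"
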