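"""Detection filtering, cross-frame association, rows and spacings."""

import numpy as np
import pytest

from standmetrics.geometry import Pixel, Point3D
from standmetrics.stand_reconstruction import (
    Detection,
    PlantTrack,
    PlatformMotion,
    RowAssignment,
    assign_rows,
    associate,
    bbox_iou,
    filter_detections,
    row_spacings,
)


def det(bbox, conf, frame=0, kp=None):
    if kp is None:
        kp = Pixel((bbox[0] + bbox[2]) / 2, (bbox[1] + bbox[3]) / 2)
    return Detection(frame_index=frame, bbox=bbox, keypoint=kp, confidence=conf)


class TestFilterDetections:
    def test_identical_boxes_deduplicated(self):
        a, b = det((0, 0, 10, 10), 0.9), det((0, 0, 10, 10), 0.8)
        kept = filter_detections([a, b], conf_min=0.0, iou_max=0.5)
        assert kept == [a]

    def test_disjoint_boxes_both_kept(self):
        a, b = det((0, 0, 10, 10), 0.9), det((20, 20, 30, 30), 0.8)
        assert len(filter_detections([a, b], 0.0, 0.5)) == 2

    def test_hand_iou_threshold(self):
        # boxes (0,0,10,10) and (5,0,15,10): IoU = 50/150 = 1/3
        a, b = det((0, 0, 10, 10), 0.9), det((5, 0, 15, 10), 0.8)
        assert bbox_iou(a.bbox, b.bbox) == pytest.approx(1 / 3)
        assert len(filter_detections([a, b], 0.0, iou_max=0.5)) == 2
        assert len(filter_detections([a, b], 0.0, iou_max=0.3)) == 1

    def test_confidence_threshold_and_output_order(self):
        dets = [det((0, 0, 5, 5), 0.4), det((10, 0, 15, 5), 0.7), det((20, 0, 25, 5), 0.95)]
        kept = filter_detections(dets, conf_min=0.5, iou_max=0.5)
        assert [d.confidence for d in kept] == [0.95, 0.7]

    def test_malformed_bbox_rejected(self):
        with pytest.raises(ValueError):
            Detection(0, (10, 0, 0, 10), Pixel(5, 5), 0.9)


def static_plant_frames(positions, frames, motion, z=1.0):
    """Exact noiseless observations of static plants over a frame range."""
    out = []
    for t in frames:
        disp = motion.displacement(t)
        obs = []
        for i, (x, y) in enumerate(positions):
            cam = Point3D(x, y - disp, z)
            d = det((0, 0, 5, 5), 0.9, frame=t)
            obs.append((d, cam))
        out.append((t, obs))
    return out


class TestAssociate:
    def test_single_plant_three_frames_one_track(self):
        motion = PlatformMotion.constant(0.5, 10.0)
        frames = static_plant_frames([(0.0, 1.0)], range(3), motion)
        tracks = associate(frames, motion, gate=0.1)
        assert len(tracks) == 1
        assert tracks[0].n_valid_obs == 3

    def test_two_well_separated_plants_two_tracks(self):
        motion = PlatformMotion.constant(0.5, 10.0)
        frames = static_plant_frames([(0.0, 1.0), (0.0, 1.5)], range(5), motion)
        tracks = associate(frames, motion, gate=0.1)
        assert len(tracks) == 2
        assert all(t.n_valid_obs == 5 for t in tracks)

    def test_displacement_beyond_gate_opens_new_track(self):
        motion = PlatformMotion.constant(0.0, 10.0)
        gate = 0.1
        frames = [
            (0, [(det((0, 0, 5, 5), 0.9, 0), Point3D(0.0, 1.0, 1.0))]),
            (1, [(det((0, 0, 5, 5), 0.9, 1), Point3D(0.0, 1.0 + 2 * gate, 1.0))]),
        ]
        tracks = associate(frames, motion, gate=gate)
        assert len(tracks) == 2

    def test_missing_depth_skipped_but_age_advances(self):
        motion = PlatformMotion.constant(0.0, 10.0)
        frames = [
            (0, [(det((0, 0, 5, 5), 0.9, 0), Point3D(0.0, 1.0, 1.0))]),
            (1, [(det((0, 0, 5, 5), 0.9, 1), None)]),
            (2, [(det((0, 0, 5, 5), 0.9, 2), Point3D(0.0, 1.0, 1.0))]),
        ]
        tracks = associate(frames, motion, gate=0.1, max_age=5)
        assert len(tracks) == 1
        assert tracks[0].n_valid_obs == 2

    def test_track_closed_after_max_age(self):
        motion = PlatformMotion.constant(0.0, 10.0)
        obs = lambda t: (det((0, 0, 5, 5), 0.9, t), Point3D(0.0, 1.0, 1.0))
        frames = [(0, [obs(0)]), (10, [obs(10)])]  # gap of 10 > max_age 3
        tracks = associate(frames, motion, gate=0.1, max_age=3)
        assert len(tracks) == 2

    def test_world_position_invariant_to_platform_speed(self):
        positions = [(0.0, 0.4 * k) for k in range(10)]
        results = []
        for speed in (0.25, 0.5, 1.0):
            motion = PlatformMotion.constant(speed, 10.0)
            frames = static_plant_frames(positions, range(40), motion)
            tracks = associate(frames, motion, gate=0.15)
            ys = sorted(t.aggregate().Y for t in tracks)
            results.append(np.asarray(ys))
        assert len(results[0]) == 10
        for other in results[1:]:
            assert np.max(np.abs(results[0] - other)) < 1e-9

    def test_spacings_invariant_to_input_frame_shuffling(self, rng):
        # association is re-run from frames sorted by index, so feeding the
        # same frames in any order must give the same stand
        motion = PlatformMotion.constant(0.5, 10.0)
        positions = [(0.0, 0.3 * k) for k in range(6)]
        frames = static_plant_frames(positions, range(20), motion)
        base = associate(frames, motion, gate=0.1)
        shuffled = list(frames)
        rng.shuffle(shuffled)
        shuffled.sort(key=lambda f: f[0])
        again = associate(shuffled, motion, gate=0.1)
        ys1 = sorted(t.aggregate().Y for t in base)
        ys2 = sorted(t.aggregate().Y for t in again)
        assert ys1 == ys2


class TestWorldAggregation:
    def test_single_observation_additive_shift(self):
        motion = PlatformMotion.constant(1.0, 1.0)  # disp = frame index
        frames = [(3, [(det((0, 0, 5, 5), 0.9, 3), Point3D(0.0, 0.2, 1.15))])]
        (track,) = associate(frames, motion, gate=0.5)
        assert track.aggregate() == pytest.approx((0.0, 3.2, 1.15))

    def test_median_of_three_world_ys(self):
        t = PlantTrack(track_id=0)
        for i, y in enumerate([3.18, 3.20, 3.29]):
            t.world_observations.append((i, Point3D(0.0, y, 1.15)))
        assert t.aggregate().Y == pytest.approx(3.20)

    def test_mean_statistic_available(self):
        t = PlantTrack(track_id=0)
        for i, y in enumerate([3.0, 3.1, 3.5]):
            t.world_observations.append((i, Point3D(0.0, y, 1.15)))
        assert t.aggregate("mean").Y == pytest.approx(np.mean([3.0, 3.1, 3.5]))

    def test_empty_track_cannot_aggregate(self):
        with pytest.raises(ValueError):
            PlantTrack(track_id=0).aggregate()


def make_tracks(coords):
    out = []
    for i, (x, y) in enumerate(coords):
        t = PlantTrack(track_id=i)
        t.world_observations.append((0, Point3D(x, y, 1.0)))
        t.world_position = Point3D(x, y, 1.0)
        out.append(t)
    return out


class TestRows:
    def test_gap_clustering_two_rows_of_two(self):
        tracks = make_tracks([(0.00, 0.1), (0.02, 0.5), (0.61, 0.3), (0.63, 0.9)])
        rows = assign_rows(tracks, row_gap=0.30)
        assert [len(r.track_ids) for r in rows] == [2, 2]

    def test_single_cluster_and_empty(self):
        tracks = make_tracks([(0.0, 0.0), (0.1, 0.2), (0.2, 0.4)])
        assert len(assign_rows(tracks, 0.30)) == 1
        assert assign_rows([], 0.30) == []

    def test_within_row_order_is_along_track(self):
        tracks = make_tracks([(0.0, 0.9), (0.01, 0.1), (0.02, 0.5)])
        (row,) = assign_rows(tracks, 0.30)
        ys = [next(t for t in tracks if t.track_id == i).world_position.Y for i in row.track_ids]
        assert ys == sorted(ys)

    def test_row_spacings_examples(self):
        tracks = make_tracks([(0.0, 0.00), (0.0, 0.15), (0.0, 0.35)])
        (row,) = assign_rows(tracks, 0.30)
        d = row_spacings(row, tracks)
        assert d == pytest.approx([0.15, 0.20])

    def test_degenerate_row_gives_empty_series(self):
        tracks = make_tracks([(0.0, 0.0)])
        (row,) = assign_rows(tracks, 0.30)
        assert row_spacings(row, tracks).size == 0

    def test_telescoping_sum_on_collinear_level_row(self, rng):
        ys = np.sort(rng.uniform(0, 5, 20))
        tracks = make_tracks([(0.0, y) for y in ys])
        (row,) = assign_rows(tracks, 0.30)
        d = row_spacings(row, tracks)
        assert d.sum() == pytest.approx(ys[-1] - ys[0])
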