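"""From per-frame detections to an ordered plant stand in world coordinates.

The camera platform drives along the crop row at a known (or tabulated)
speed, so a static plant appears at a camera-frame along-track coordinate
that decreases as the platform advances.  Adding the platform displacement
at each frame to the camera-frame along-track coordinate puts every
observation of the same plant at (nearly) the same world point; identity
maintenance then reduces to nearest-neighbor gating in world coordinates.

Appearance-based multi-object trackers (the DeepSORT family) maintain
identity through learned appearance embeddings; those need a trained
re-identification network and bring little on a static scene with known
ego-motion.  This module instead implements a motion-only greedy tracker
with ego-motion-compensated prediction and a metric distance gate, which
preserves the identity-maintenance contract the downstream spacing
statistics depend on (one track per physical plant, stable across frames).

Pipeline order: filter_detections -> associate -> assign_rows ->
row_spacings, with per-track world positions aggregated as coordinate-wise
medians over all valid observations (robust to isolated depth failures and
occasional mis-associations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import Pixel, Point3D, spacing_3d

__all__ = [
    "Detection",
    "PlatformMotion",
    "PlantTrack",
    "RowAssignment",
    "bbox_iou",
    "filter_detections",
    "associate",
    "assign_rows",
    "row_spacings",
]


@dataclass
class Detection:
    """One per-frame plant observation from the keypoint detector."""

    frame_index: int
    bbox: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    keypoint: Pixel
    confidence: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"malformed bbox {self.bbox}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")

    @property
    def bbox_center(self) -> Pixel:
        x0, y0, x1, y1 = self.bbox
        return Pixel((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class PlatformMotion:
    """Along-track platform displacement as a function of frame index.

    Either constant speed (displacement = speed * frame / frame_rate) or an
    explicit per-frame displacement table.  Displacement is measured in
    meters from the first frame and must be non-decreasing.
    """

    speed: float | None = None
    frame_rate: float | None = None
    table: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.table is None:
            if self.speed is None or self.frame_rate is None or self.frame_rate <= 0:
                raise ValueError(
                    "constant-speed motion needs speed and a positive frame_rate"
                )
        else:
            d = [self.table[k] for k in sorted(self.table)]
            if any(b < a for a, b in zip(d, d[1:])):
                raise ValueError("displacement table must be non-decreasing")

    @classmethod
    def constant(cls, speed_mps: float, frame_rate: float) -> "PlatformMotion":
        return cls(speed=speed_mps, frame_rate=frame_rate)

    @classmethod
    def from_table(cls, frame_index: Sequence[int], displacement_m: Sequence[float]) -> "PlatformMotion":
        return cls(table=dict(zip((int(i) for i in frame_index), map(float, displacement_m))))

    def displacement(self, frame_index: int) -> float:
        if self.table is not None:
            try:
                return self.table[int(frame_index)]
            except KeyError:
                raise KeyError(f"no displacement for frame {frame_index}") from None
        return self.speed * frame_index / self.frame_rate


@dataclass
class PlantTrack:
    """An identity-maintained plant: camera-frame observations plus world position."""

    track_id: int
    observations: list[tuple[int, Point3D]] = field(default_factory=list)
    world_observations: list[tuple[int, Point3D]] = field(default_factory=list)
    world_position: Point3D | None = None
    last_frame: int = -1

    @property
    def n_valid_obs(self) -> int:
        return len(self.world_observations)

    def aggregate(self, statistic: str = "median") -> Point3D:
        """Fuse world observations into one position, coordinate-wise."""
        if not self.world_observations:
            raise ValueError(f"track {self.track_id} has no valid observations")
        pts = np.array([p for _, p in self.world_observations], dtype=float)
        fn = np.median if statistic == "median" else np.mean
        x, y, z = (float(fn(pts[:, k])) for k in range(3))
        return Point3D(x, y, z)


@dataclass
class RowAssignment:
    """One crop row: member track ids ordered by world along-track coordinate."""

    row_id: int
    track_ids: list[int]


def bbox_iou(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> float:
    """Intersection-over-union of two axis-aligned boxes."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    if inter == 0.0:
        return 0.0
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def filter_detections(
    dets: Sequence[Detection], conf_min: float = 0.5, iou_max: float = 0.5
) -> list[Detection]:
    """Confidence thresholding followed by greedy non-maximum suppression.

    Detections below ``conf_min`` are dropped; the survivors are visited in
    descending confidence (ties broken by original order) and each one
    suppresses any later detection whose bbox IoU with it exceeds
    ``iou_max``.  Returns the kept detections sorted by confidence
    descending.
    """
    if not (0.0 <= conf_min <= 1.0 and 0.0 <= iou_max <= 1.0):
        raise ValueError("conf_min and iou_max must be in [0, 1]")
    candidates = [(i, d) for i, d in enumerate(dets) if d.confidence >= conf_min]
    candidates.sort(key=lambda t: (-t[1].confidence, t[0]))
    kept: list[Detection] = []
    for _, d in candidates:
        if all(bbox_iou(d.bbox, k.bbox) <= iou_max for k in kept):
            kept.append(d)
    return kept


def associate(
    frames: Sequence[tuple[int, Sequence[tuple[Detection, Point3D | None]]]],
    motion: PlatformMotion,
    gate: float = 0.10,
    max_age: int = 5,
) -> list[PlantTrack]:
    """Greedy motion-gated cross-frame association into plant tracks.

    ``frames`` is a sequence of (frame_index, [(detection, camera_point)])
    pairs ordered by frame index; ``camera_point`` is None when depth
    extraction failed for that detection (the detection is then skipped —
    it adds no observation, but track ages still advance with the frame).

    Each camera point is shifted into world coordinates using the platform
    displacement at its frame; detections are matched one-to-one to live
    tracks by ascending world distance to the track's running world
    position, accepting only matches within ``gate`` meters.  Unmatched
    detections open new tracks; a track unmatched for more than ``max_age``
    consecutive frames is closed to new matches (but still reported).
    Tie-breaking is fully deterministic: ascending distance, then ascending
    track id, then detection order within the frame.
    """
    if gate <= 0:
        raise ValueError("gate must be positive")
    tracks: list[PlantTrack] = []
    live: list[PlantTrack] = []
    next_id = 0
    for frame_index, obs in frames:
        # close tracks that have gone unmatched for more than max_age frames
        live = [t for t in live if frame_index - t.last_frame <= max_age]
        disp = motion.displacement(frame_index)
        world_pts: list[tuple[int, Detection, Point3D]] = []
        for j, (det, cam) in enumerate(obs):
            if cam is None:
                continue
            world_pts.append((j, det, Point3D(cam.X, cam.Y + disp, cam.Z)))
        # candidate matches: (distance, track slot, detection slot)
        pairs: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(live):
            pred = tr.aggregate()
            for j, _, wp in world_pts:
                d = spacing_3d(pred, wp)
                if d <= gate:
                    pairs.append((d, ti, j))
        pairs.sort(key=lambda t: (t[0], live[t[1]].track_id, t[2]))
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        assignment: dict[int, int] = {}
        for d, ti, j in pairs:
            if ti in matched_tracks or j in matched_dets:
                continue
            matched_tracks.add(ti)
            matched_dets.add(j)
            assignment[j] = ti
        for j, det, wp in world_pts:
            cam = obs[j][1]
            if j in assignment:
                tr = live[assignment[j]]
            else:
                tr = PlantTrack(track_id=next_id)
                next_id += 1
                tracks.append(tr)
                live.append(tr)
            tr.observations.append((frame_index, cam))
            tr.world_observations.append((frame_index, wp))
            tr.last_frame = frame_index
    reported = [t for t in tracks if t.n_valid_obs > 0]
    for t in reported:
        t.world_position = t.aggregate()
    return reported


def assign_rows(tracks: Sequence[PlantTrack], row_gap: float = 0.30) -> list[RowAssignment]:
    """Group tracks into crop rows by 1D gap clustering on cross-track X.

    Tracks are sorted by world X; a gap larger than ``row_gap`` meters
    starts a new row.  Within each row, members are ordered by along-track
    Y (ties by track id) — the order in which the planter dropped them.
    """
    if row_gap <= 0:
        raise ValueError("row_gap must be positive")
    ts = [t for t in tracks if t.world_position is not None]
    if not ts:
        return []
    ts.sort(key=lambda t: (t.world_position.X, t.track_id))
    rows: list[list[PlantTrack]] = [[ts[0]]]
    for prev, cur in zip(ts, ts[1:]):
        if cur.world_position.X - prev.world_position.X > row_gap:
            rows.append([cur])
        else:
            rows[-1].append(cur)
    out = []
    for rid, members in enumerate(rows):
        members.sort(key=lambda t: (t.world_position.Y, t.track_id))
        out.append(RowAssignment(row_id=rid, track_ids=[t.track_id for t in members]))
    return out


def row_spacings(row: RowAssignment, tracks: Iterable[PlantTrack]) -> np.ndarray:
    """Ordered spacings (meters) between consecutive plants of one row.

    Length is one less than the member count; an under-populated row yields
    an empty array.
    """
    by_id = {t.track_id: t for t in tracks}
    pts = [by_id[tid].world_position for tid in row.track_ids]
    if len(pts) < 2:
        return np.empty(0, dtype=float)
    return np.array(
        [spacing_3d(a, b) for a, b in zip(pts, pts[1:])], dtype=float
    )


def tracks_to_frame(tracks: Sequence[PlantTrack], rows: Sequence[RowAssignment]) -> pd.DataFrame:
    """Tabulate tracks with their row assignment and within-row order."""
    rec = []
    row_of = {tid: (r.row_id, k) for r in rows for k, tid in enumerate(r.track_ids)}
    for t in tracks:
        rid, order = row_of.get(t.track_id, (-1, -1))
        wp = t.world_position
        rec.append(
            dict(
                track_id=t.track_id,
                row_id=rid,
                order_in_row=order,
                X_m=wp.X,
                Y_m=wp.Y,
                Z_m=wp.Z,
                n_valid_obs=t.n_valid_obs,
            )
        )
    df = pd.DataFrame.from_records(
        rec,
        columns=["track_id", "row_id", "order_in_row", "X_m", "Y_m", "Z_m", "n_valid_obs"],
    )
    return df.sort_values(["row_id", "order_in_row"]).reset_index(drop=True)
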