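"""End-to-end measurement pipeline over an on-disk run directory.

Stages, in order: detection filtering (confidence + NMS), RGB/depth frame
alignment, robust depth extraction at each keypoint, pinhole
back-projection to camera coordinates, motion-compensated cross-frame
association into plant tracks, world-frame aggregation, row clustering,
within-row spacing computation, and the sowing-quality evaluation.  Every
stage logs one summary line with its in/out counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from . import sowing_quality
from .geometry import Pixel, align_depth_index, back_project, extract_depth
from .sowing_quality import QualityReport, SpacingSeries
from .stand_reconstruction import (
    PlatformMotion,
    associate,
    assign_rows,
    filter_detections,
    row_spacings,
    tracks_to_frame,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("standmetrics")


@dataclass
class RunConfig:
    """All knobs of one measurement run.

    ``depth_anchor`` selects where the depth window is sampled: at the
    detected keypoint (default; the back-projected point is the keypoint,
    so sampling elsewhere would introduce parallax) or at the bbox center.
    ``mode='track'`` aggregates across frames via tracking;
    ``'per_frame'`` measures spacings among detections of each single
    frame without identity maintenance (single-image use).
    """

    target_spacing: float = 0.20  # m
    conf_min: float = 0.5
    iou_max: float = 0.5
    gate: float | None = None  # m; default 0.5 * target_spacing
    max_age: int = 5
    row_gap: float = 0.30  # m
    depth_window: int = 3  # px, odd
    depth_anchor: str = "keypoint"  # or "bbox_center"
    mode: str = "track"  # or "per_frame"
    speed_mps: float | None = None  # overrides motion.csv when set
    aggregate: str = "median"
    sigma_formula: str = "corrected"
    cv_normalize_by_mean: bool = False

    def __post_init__(self) -> None:
        if self.gate is None:
            self.gate = 0.5 * self.target_spacing
        if self.depth_anchor not in ("keypoint", "bbox_center"):
            raise ValueError("depth_anchor must be 'keypoint' or 'bbox_center'")
        if self.mode not in ("track", "per_frame"):
            raise ValueError("mode must be 'track' or 'per_frame'")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")


@dataclass
class PipelineResult:
    """Everything one run produced, in memory."""

    tracks_table: pd.DataFrame
    spacings_per_row: list[SpacingSeries]
    pooled: SpacingSeries
    report: QualityReport  # pooled across rows
    per_row_reports: list[QualityReport | None]
    n_detections_in: int = 0
    n_detections_kept: int = 0
    n_tracks: int = 0
    n_rows: int = 0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tracks_table.to_csv(out / "tracks.csv", index=False, float_format=smio.FLOAT_FMT)
        rec = []
        for rid, series in enumerate(self.spacings_per_row):
            for order, d in enumerate(series.spacings):
                rec.append(dict(row_id=rid, order=order, spacing_m=d))
        pd.DataFrame(rec, columns=["row_id", "order", "spacing_m"]).to_csv(
            out / "spacings.csv", index=False, float_format=smio.FLOAT_FMT
        )
        doc = self.report.to_dict()
        doc["per_row"] = [r.to_dict() if r is not None else None for r in self.per_row_reports]
        doc["n_tracks"] = self.n_tracks
        doc["n_rows"] = self.n_rows
        (out / "report.json").write_text(json.dumps(doc, indent=1))


def run_pipeline(run_dir: str | Path, cfg: RunConfig | None = None) -> PipelineResult:
    """Run the full measurement over a run directory (see io module layout)."""
    cfg = cfg or RunConfig()
    run = Path(run_dir)
    K, clock, _camera_height = smio.read_intrinsics(run / "intrinsics.cfg")
    frames_dets = smio.read_detections(run / "detections.csv")
    n_in = sum(len(v) for v in frames_dets.values())
    if cfg.speed_mps is not None:
        motion = PlatformMotion.constant(cfg.speed_mps, clock.rgb_rate)
    elif (run / "motion.csv").exists():
        motion = smio.read_motion(run / "motion.csv")
    else:
        raise FileNotFoundError(f"{run}: no motion.csv and no speed_mps configured")

    depth_dir = run / "depth"
    frames = []
    n_kept = 0
    n_depth_missing = 0
    for frame_index, dets in frames_dets.items():
        kept = filter_detections(dets, conf_min=cfg.conf_min, iou_max=cfg.iou_max)
        n_kept += len(kept)
        t_depth = align_depth_index(frame_index, clock)
        dpath = smio.depth_path(depth_dir, t_depth)
        depth = smio.read_depth(dpath, frame_index=t_depth) if dpath.exists() else None
        obs = []
        for det in kept:
            point = None
            if depth is not None:
                anchor = det.keypoint if cfg.depth_anchor == "keypoint" else det.bbox_center
                z = extract_depth(depth, anchor, window=cfg.depth_window)
                if z is None:
                    n_depth_missing += 1
                else:
                    point = back_project(det.keypoint, z, K)
            obs.append((det, point))
        frames.append((frame_index, obs))
    log.info(
        "detections: %d in, %d kept after filtering; %d depth-missing observations",
        n_in,
        n_kept,
        n_depth_missing,
    )

    if cfg.mode == "per_frame":
        return _per_frame_result(frames, cfg, n_in, n_kept)

    tracks = associate(frames, motion, gate=cfg.gate, max_age=cfg.max_age)
    for t in tracks:
        t.world_position = t.aggregate(cfg.aggregate)
    log.info("tracking: %d frames -> %d tracks", len(frames), len(tracks))
    rows = assign_rows(tracks, row_gap=cfg.row_gap)
    log.info("rows: %d tracks -> %d rows", len(tracks), len(rows))
    spacings_per_row = [
        SpacingSeries(row_spacings(r, tracks), cfg.target_spacing) for r in rows
    ]
    return _finalize(tracks, rows, spacings_per_row, cfg, n_in, n_kept)


def _finalize(tracks, rows, spacings_per_row, cfg, n_in, n_kept) -> PipelineResult:
    pooled_d = (
        np.concatenate([s.spacings for s in spacings_per_row])
        if spacings_per_row
        else np.empty(0)
    )
    pooled = SpacingSeries(pooled_d, cfg.target_spacing)
    report = sowing_quality.evaluate(
        pooled, sigma_formula=cfg.sigma_formula, cv_normalize_by_mean=cfg.cv_normalize_by_mean
    )
    per_row = []
    for s in spacings_per_row:
        if len(s) == 0:
            log.warning("row with fewer than two plants: no spacing series")
            per_row.append(None)
        else:
            per_row.append(
                sowing_quality.evaluate(
                    s,
                    sigma_formula=cfg.sigma_formula,
                    cv_normalize_by_mean=cfg.cv_normalize_by_mean,
                )
            )
    table = tracks_to_frame(tracks, rows)
    log.info(
        "evaluation: %d intervals pooled across %d rows", len(pooled), len(rows)
    )
    return PipelineResult(
        tracks_table=table,
        spacings_per_row=spacings_per_row,
        pooled=pooled,
        report=report,
        per_row_reports=per_row,
        n_detections_in=n_in,
        n_detections_kept=n_kept,
        n_tracks=len(tracks),
        n_rows=len(rows),
    )


def _per_frame_result(frames, cfg: RunConfig, n_in: int, n_kept: int) -> PipelineResult:
    """Spacings among detections within each frame, no identity maintenance."""
    all_d = []
    from .geometry import spacing_3d

    for _, obs in frames:
        pts = sorted(
            (p for _, p in obs if p is not None), key=lambda p: (p.Y, p.X)
        )
        all_d.extend(spacing_3d(a, b) for a, b in zip(pts, pts[1:]))
    pooled = SpacingSeries(np.asarray(all_d), cfg.target_spacing)
    report = sowing_quality.evaluate(
        pooled, sigma_formula=cfg.sigma_formula, cv_normalize_by_mean=cfg.cv_normalize_by_mean
    )
    empty = pd.DataFrame(
        columns=["track_id", "row_id", "order_in_row", "X_m", "Y_m", "Z_m", "n_valid_obs"]
    )
    return PipelineResult(
        tracks_table=empty,
        spacings_per_row=[pooled],
        pooled=pooled,
        report=report,
        per_row_reports=[report],
        n_detections_in=n_in,
        n_detections_kept=n_kept,
        n_tracks=0,
        n_rows=1,
    )
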