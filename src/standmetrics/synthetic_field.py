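"""Synthetic planted-row scenes for end-to-end pipeline validation.

No public dataset of nadir seedling imagery with aligned depth exists for
this measurement task, so validation rests on a generative model of the
acquisition: a planter drops seeds at nominal multiples of the target
spacing along each row, with three kinds of departure from the ideal
stand —

* **miss** (probability ``p_miss``): no plant emerges at a drop point, so
  the surviving gap is lengthened by one target spacing per consecutive
  miss (driving the Miss Index);
* **multiple** (probability ``p_multiple``): an extra plant emerges near a
  drop point, creating a short gap (driving the Multiple Index);
* **placement noise** (``spacing_sd``): Gaussian along-track scatter of
  each emerged plant about its nominal drop point.

A nadir camera at ``camera_height`` (the field rig flies ~1.15 m above
ground) travels along the row at constant speed, projecting every plant in
its frustum to a keypoint pixel (with optional detection jitter) and
rendering a depth map: ground depth everywhere except a small canopy disc
at each plant, Gaussian depth noise, independent per-pixel dropout, and
millimeter quantization — the failure modes of a stereo depth sensor.

Two independent random streams are used (stand layout vs. acquisition
noise), sub-seeded from the configs, so changing camera noise never
changes the simulated stand.  Ground truth carries the true plant
positions, the true per-row spacing series, and the oracle quality report
computed from them, which downstream pipeline runs are compared against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import sowing_quality
from .geometry import CameraIntrinsics, Point3D, project
from .sowing_quality import QualityReport, SpacingSeries

__all__ = [
    "StandConfig",
    "AcquisitionConfig",
    "GroundTruth",
    "simulate_stand",
    "render_observations",
    "end_to_end_fixture",
    "expected_miss_index",
]

# default intrinsics: the field rig's 1100x620 nadir camera; at 1.15 m
# height the frustum spans ~2.1 m cross-track x ~1.2 m along-track
DEFAULT_INTRINSICS = CameraIntrinsics(
    fx=600.0, fy=600.0, cx=550.0, cy=310.0, width=1100, height=620
)

# same frustum at ~1/4.3 the pixel count: renders fast, keeps the geometry
DESK_INTRINSICS = CameraIntrinsics(
    fx=140.0, fy=140.0, cx=128.0, cy=72.0, width=256, height=144
)


@dataclass(frozen=True)
class StandConfig:
    """Generative parameters of the planted stand (what the planter did)."""

    target_spacing: float = 0.20  # m; field trials use 0.15/0.20/0.25
    n_positions: int = 101  # nominal drop points per row
    p_miss: float = 0.0
    p_multiple: float = 0.0
    spacing_sd: float = 0.008  # m along-track emergence scatter
    multiple_offset_sd: float = 0.03  # m offset of the extra plant
    n_rows: int = 1
    row_spacing: float = 0.60  # m between rows
    cross_track_sd: float = 0.01  # m cross-track scatter within a row
    plant_height_mean: float = 0.15  # m, five-leaf-stage seedlings
    plant_height_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_miss <= 1 and 0 <= self.p_multiple <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")
        if self.n_positions < 2:
            raise ValueError("need at least two drop points")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera, platform and sensor-noise parameters of a survey pass."""

    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
    camera_height: float = 1.15  # m above ground, lens pointing down
    speed: float = 0.556  # m/s (2 km/h survey speed)
    rgb_rate: float = 15.0  # frames/s
    depth_rate: float = 15.0
    pixel_jitter_sd: float = 0.0  # px, keypoint localization noise
    depth_noise_sd: float = 0.0  # m, per-pixel depth noise
    p_invalid_pixel: float = 0.0  # stereo-matching dropout
    detection_conf_range: tuple[float, float] = (0.80, 1.00)
    plant_radius: float = 0.06  # m, rendered canopy radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.camera_height <= 0 or self.speed < 0:
            raise ValueError("camera_height must be positive, speed non-negative")
        if not (0 <= self.p_invalid_pixel <= 1):
            raise ValueError("p_invalid_pixel must be in [0, 1]")
        if self.rgb_rate <= 0 or self.depth_rate <= 0:
            raise ValueError("frame rates must be positive")


@dataclass
class Plant:
    """A true plant: world position of its keypoint and its height."""

    X: float  # cross-track, m
    Y: float  # along-track, m
    height: float  # m above ground
    row: int


@dataclass
class GroundTruth:
    """True stand: plants, per-row spacing series, and the oracle report."""

    plants: list[Plant]
    spacings_per_row: list[SpacingSeries]
    oracle: QualityReport
    config: StandConfig

    @property
    def pooled_spacings(self) -> SpacingSeries:
        all_d = np.concatenate([s.spacings for s in self.spacings_per_row]) if self.spacings_per_row else np.empty(0)
        return SpacingSeries(all_d, self.config.target_spacing)

    def keypoint_world(self, acq: AcquisitionConfig) -> list[Point3D]:
        """World 3D keypoints as the camera sees them (Z = height above plant)."""
        return [
            Point3D(p.X, p.Y, acq.camera_height - p.height) for p in self.plants
        ]


def simulate_stand(cfg: StandConfig) -> GroundTruth:
    """Draw one stand realization and its ground-truth quality report.

    Drop point k of row r sits nominally at along-track k * target_spacing,
    cross-track r * row_spacing (centered about 0).  Reproducible from
    ``cfg.seed`` alone.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x57A2D]))
    plants: list[Plant] = []
    x0 = -(cfg.n_rows - 1) * cfg.row_spacing / 2.0
    for r in range(cfg.n_rows):
        for k in range(cfg.n_positions):
            nominal_y = k * cfg.target_spacing
            # draw all randomness unconditionally so the stand layout for
            # position k is stable under changes to p_miss/p_multiple order
            u_miss = rng.uniform()
            u_mult = rng.uniform()
            dy = rng.normal(0.0, cfg.spacing_sd)
            dx = rng.normal(0.0, cfg.cross_track_sd)
            h = max(0.02, rng.normal(cfg.plant_height_mean, cfg.plant_height_sd))
            extra_dy = rng.normal(0.0, cfg.multiple_offset_sd)
            extra_h = max(0.02, rng.normal(cfg.plant_height_mean, cfg.plant_height_sd))
            if u_miss < cfg.p_miss:
                continue
            plants.append(Plant(X=x0 + r * cfg.row_spacing + dx, Y=nominal_y + dy, height=h, row=r))
            if u_mult < cfg.p_multiple:
                plants.append(
                    Plant(
                        X=x0 + r * cfg.row_spacing + dx,
                        Y=nominal_y + dy + extra_dy,
                        height=extra_h,
                        row=r,
                    )
                )
    spacings_per_row: list[SpacingSeries] = []
    for r in range(cfg.n_rows):
        members = sorted((p for p in plants if p.row == r), key=lambda p: p.Y)
        # true spacing = 3D Euclidean distance between adjacent keypoints,
        # exactly the quantity the measurement pipeline reconstructs
        d = np.array(
            [
                np.sqrt(
                    (b.X - a.X) ** 2 + (b.Y - a.Y) ** 2 + (b.height - a.height) ** 2
                )
                for a, b in zip(members, members[1:])
            ],
            dtype=float,
        )
        spacings_per_row.append(SpacingSeries(d, cfg.target_spacing))
    pooled = (
        np.concatenate([s.spacings for s in spacings_per_row])
        if spacings_per_row
        else np.empty(0)
    )
    oracle = sowing_quality.evaluate(SpacingSeries(pooled, cfg.target_spacing))
    return GroundTruth(
        plants=plants, spacings_per_row=spacings_per_row, oracle=oracle, config=cfg
    )


def _frame_count(truth: GroundTruth, acq: AcquisitionConfig) -> int:
    """Frames needed for the frustum to sweep past the whole stand."""
    y_max = max((p.Y for p in truth.plants), default=0.0)
    half_view = acq.intrinsics.height / 2.0 * acq.camera_height / acq.intrinsics.fy
    travel = y_max + 2.0 * half_view
    if acq.speed == 0:
        return 1
    return int(np.ceil(travel / acq.speed * acq.rgb_rate)) + 1


def render_observations(truth: GroundTruth, acq: AcquisitionConfig):
    """Render per-frame detections and depth maps of a moving survey pass.

    Yields ``(frame_index, displacement_m, detections, depth_mm)`` where
    ``detections`` is a list of dicts with bbox, keypoint pixel and
    confidence, and ``depth_mm`` is the uint16 millimeter depth image
    (0 = invalid pixel).  The camera center at frame t sits over world
    (0, displacement(t)); camera-frame along-track Y = world Y - displacement.
    """
    K = acq.intrinsics
    rng = np.random.default_rng(np.random.SeedSequence([acq.seed, 0xCA3E6A]))
    n_frames = _frame_count(truth, acq)
    kps = truth.keypoint_world(acq)
    ground_mm = acq.camera_height * 1000.0
    yy, xx = np.mgrid[0 : K.height, 0 : K.width]
    for t in range(n_frames):
        disp = acq.speed * t / acq.rgb_rate
        depth_m = np.full((K.height, K.width), acq.camera_height, dtype=float)
        dets = []
        for plant, wp in zip(truth.plants, kps):
            cam = Point3D(wp.X, wp.Y - disp, wp.Z)
            px = project(cam, K)
            if not (0 <= px.x <= K.width - 1 and 0 <= px.y <= K.height - 1):
                continue
            # canopy: a disc at the plant's height around its keypoint
            r_px = acq.plant_radius * K.fx / cam.Z
            disc = (xx - px.x) ** 2 + (yy - px.y) ** 2 <= r_px**2
            depth_m[disc] = cam.Z
            kx = px.x + rng.normal(0.0, acq.pixel_jitter_sd)
            ky = px.y + rng.normal(0.0, acq.pixel_jitter_sd)
            kx = float(np.clip(kx, 0, K.width - 1))
            ky = float(np.clip(ky, 0, K.height - 1))
            conf = float(rng.uniform(*acq.detection_conf_range))
            half = max(2.0, r_px)
            dets.append(
                dict(
                    x_min=max(0.0, kx - half),
                    y_min=max(0.0, ky - half),
                    x_max=min(K.width - 1.0, kx + half),
                    y_max=min(K.height - 1.0, ky + half),
                    kp_x=kx,
                    kp_y=ky,
                    confidence=conf,
                )
            )
        if acq.depth_noise_sd > 0:
            depth_m = depth_m + rng.normal(0.0, acq.depth_noise_sd, depth_m.shape)
        depth_mm = np.clip(np.rint(depth_m * 1000.0), 0, 65535).astype(np.uint16)
        if acq.p_invalid_pixel > 0:
            drop = rng.uniform(size=depth_mm.shape) < acq.p_invalid_pixel
            depth_mm[drop] = 0
        yield t, disp, dets, depth_mm


def end_to_end_fixture(
    stand: StandConfig, acq: AcquisitionConfig, out_dir: str | Path
) -> GroundTruth:
    """Write a complete synthetic run directory and return its ground truth.

    Layout: ``detections.csv``, ``depth/depth_<frame:06d>.pgm``,
    ``motion.csv``, ``intrinsics.cfg``, ``truth.json``.  All distributions
    here are this simulator's own model of the acquisition, recorded as
    such in ``truth.json``.
    """
    from . import io as smio  # deferred: io imports nothing from here

    out = Path(out_dir)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    truth = simulate_stand(stand)
    det_rows = []
    motion_rows = []
    for t, disp, dets, depth_mm in render_observations(truth, acq):
        smio.write_depth(out / "depth" / f"depth_{t:06d}.pgm", depth_mm)
        motion_rows.append((t, disp))
        for d in dets:
            det_rows.append(
                dict(frame_index=t, timestamp_s=t / acq.rgb_rate, **d)
            )
    smio.write_detections(out / "detections.csv", det_rows)
    smio.write_motion(out / "motion.csv", motion_rows)
    smio.write_intrinsics(
        out / "intrinsics.cfg",
        acq.intrinsics,
        rgb_rate=acq.rgb_rate,
        depth_rate=acq.depth_rate,
        camera_height_m=acq.camera_height,
    )
    truth_doc = {
        "note": "synthetic stand; all generative distributions are the simulator's own",
        "stand_config": asdict(stand),
        "n_plants": len(truth.plants),
        "plants": [
            dict(X=p.X, Y=p.Y, height=p.height, row=p.row) for p in truth.plants
        ],
        "true_spacings_per_row": [list(map(float, s.spacings)) for s in truth.spacings_per_row],
        "target_spacing_m": stand.target_spacing,
        "oracle_report": truth.oracle.to_dict(),
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return truth


def expected_miss_index(
    p_miss: float,
    p_multiple: float = 0.0,
    n_positions: int = 100_000,
    target_spacing: float = 0.20,
    spacing_sd: float = 0.0,
    seed: int = 12345,
) -> float:
    """Monte-Carlo estimate of the expected Miss Index of the stand model.

    Direct brute-force simulation: draw one very long row from the same
    miss/multiple process, form the skip-lengthened gaps, bin them, and
    return MI.  Serves as the independent oracle for the stand simulator's
    quality reports.
    """
    cfg = StandConfig(
        target_spacing=target_spacing,
        n_positions=n_positions,
        p_miss=p_miss,
        p_multiple=p_multiple,
        spacing_sd=spacing_sd,
        cross_track_sd=0.0,
        seed=seed,
    )
    return simulate_stand(cfg).oracle.mi_pct
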