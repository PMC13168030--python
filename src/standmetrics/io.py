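"""Readers and writers for the pipeline's on-disk formats.

* detections: CSV with header
  ``frame_index,timestamp_s,x_min,y_min,x_max,y_max,kp_x,kp_y,confidence``
* depth maps: binary 16-bit single-channel PGM (P5, maxval 65535),
  value = depth in millimeters, 0 = invalid pixel, one file per frame
  named ``depth_<frame_index:06d>.pgm``
* platform motion: CSV ``frame_index,displacement_m`` (or a constant
  ``speed_mps`` in the run config)
* intrinsics: YAML-style key/value config with
  fx, fy, cx, cy, width, height, rgb_rate, depth_rate, camera_height_m
* tracks/rows: CSV ``track_id,row_id,order_in_row,X_m,Y_m,Z_m,n_valid_obs``

Floating-point CSV output uses 9 significant digits so that re-runs are
byte-comparable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import CameraIntrinsics, DepthFrame, FrameClock, Pixel
from .stand_reconstruction import Detection, PlatformMotion

__all__ = [
    "read_detections",
    "write_detections",
    "read_depth",
    "write_depth",
    "read_motion",
    "write_motion",
    "read_intrinsics",
    "write_intrinsics",
    "depth_path",
]

DETECTION_COLUMNS = [
    "frame_index",
    "timestamp_s",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "kp_x",
    "kp_y",
    "confidence",
]

FLOAT_FMT = "%.9g"


def read_detections(path: str | Path) -> dict[int, list[Detection]]:
    """Load a detection table grouped by frame, frames sorted ascending.

    Rows that violate the schema (bad bbox, confidence outside [0, 1],
    non-numeric fields) are rejected with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    frames: dict[int, list[Detection]] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            det = Detection(
                frame_index=int(row.frame_index),
                bbox=(
                    float(row.x_min),
                    float(row.y_min),
                    float(row.x_max),
                    float(row.y_max),
                ),
                keypoint=Pixel(float(row.kp_x), float(row.kp_y)),
                confidence=float(row.confidence),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: bad detection row: {exc}") from exc
        frames.setdefault(det.frame_index, []).append(det)
    return dict(sorted(frames.items()))


def write_detections(path: str | Path, rows: Iterable[Mapping]) -> None:
    df = pd.DataFrame(list(rows), columns=DETECTION_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def depth_path(depth_dir: str | Path, frame_index: int) -> Path:
    return Path(depth_dir) / f"depth_{frame_index:06d}.pgm"


def read_depth(path: str | Path, frame_index: int = 0) -> DepthFrame:
    """Read a millimeter-valued P5 PGM depth map; zeros become invalid pixels."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic != b"P5":
        raise ValueError(f"{path}: not a binary (P5) PGM depth map")
    raw = np.asarray(iio.imread(path))
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel depth map")
    return DepthFrame.from_millimeters(raw, frame_index=frame_index)


def write_depth(path: str | Path, depth_mm: np.ndarray) -> None:
    """Write a uint16 millimeter depth image as binary PGM (maxval 65535)."""
    arr = np.asarray(depth_mm)
    if arr.dtype != np.uint16:
        if (arr < 0).any() or (arr > 65535).any():
            raise ValueError("depth values outside the uint16 millimeter range")
        arr = arr.astype(np.uint16)
    iio.imwrite(Path(path), arr)


def read_motion(path: str | Path) -> PlatformMotion:
    df = pd.read_csv(path)
    for col in ("frame_index", "displacement_m"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PlatformMotion.from_table(df["frame_index"], df["displacement_m"])


def write_motion(path: str | Path, rows: Sequence[tuple[int, float]]) -> None:
    df = pd.DataFrame(rows, columns=["frame_index", "displacement_m"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_intrinsics(path: str | Path) -> tuple[CameraIntrinsics, FrameClock, float]:
    """Load camera config: (intrinsics, frame clock, camera height in m)."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        K = CameraIntrinsics(
            fx=float(doc["fx"]),
            fy=float(doc["fy"]),
            cx=float(doc["cx"]),
            cy=float(doc["cy"]),
            width=int(doc["width"]),
            height=int(doc["height"]),
        )
        clock = FrameClock(rgb_rate=float(doc["rgb_rate"]), depth_rate=float(doc["depth_rate"]))
        height = float(doc["camera_height_m"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing camera config key {exc}") from exc
    return K, clock, height


def write_intrinsics(
    path: str | Path,
    K: CameraIntrinsics,
    rgb_rate: float,
    depth_rate: float,
    camera_height_m: float,
) -> None:
    doc = dict(
        fx=float(K.fx),
        fy=float(K.fy),
        cx=float(K.cx),
        cy=float(K.cy),
        width=int(K.width),
        height=int(K.height),
        rgb_rate=float(rgb_rate),
        depth_rate=float(depth_rate),
        camera_height_m=float(camera_height_m),
    )
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
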