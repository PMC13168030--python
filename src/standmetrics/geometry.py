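"""Pinhole camera geometry for nadir-view plant localization.

A downward-looking stereo camera rides over a crop row and delivers, per
frame, an RGB image (in which a detector finds one keypoint per seedling)
and a dense depth map in millimeters.  This module holds the geometric
core of the measurement: aligning RGB frames with depth frames captured at
a possibly different rate, extracting a robust depth value at a pixel from
a noisy depth map with invalid pixels, back-projecting pixel + depth
through the intrinsics into metric camera coordinates, and computing the
3D Euclidean spacing between two reconstructed points.

Axis convention: pixel x is the image column (cross-track, perpendicular
to platform travel), pixel y is the image row (along-track, the travel
direction).  Camera-frame X/Y follow the same directions in meters; Z is
depth from the camera toward the scene, so Z > 0 for everything observed.
Pixels are 0-based with the origin at the top-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "Pixel",
    "Point3D",
    "DepthFrame",
    "FrameClock",
    "align_depth_index",
    "extract_depth",
    "back_project",
    "project",
    "spacing_3d",
]


class Pixel(NamedTuple):
    """Image location in pixels: x = column (cross-track), y = row (along-track)."""

    x: float
    y: float


class Point3D(NamedTuple):
    """Metric camera/world point: X cross-track, Y along-track, Z depth (meters)."""

    X: float
    Y: float
    Z: float


@dataclass(frozen=True)
class CameraIntrinsics:
    """Ideal pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def contains(self, p: Pixel) -> bool:
        return 0 <= p.x < self.width and 0 <= p.y < self.height


@dataclass(frozen=True)
class FrameClock:
    """Acquisition rates of the RGB and depth streams, frames per second."""

    rgb_rate: float
    depth_rate: float

    def __post_init__(self) -> None:
        if not (self.rgb_rate > 0 and self.depth_rate > 0):
            raise ValueError("frame rates must be positive")


@dataclass
class DepthFrame:
    """One depth map in meters with an explicit validity mask.

    Raw sensor files carry unsigned millimeter integers where 0 marks a
    stereo-matching failure; on load those pixels become invalid and the
    rest are converted to meters.  ``values`` at invalid pixels are
    unspecified and must never influence a computation.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 2:
            raise ValueError("values and valid_mask must be matching 2D arrays")

    @classmethod
    def from_millimeters(cls, raw: np.ndarray, frame_index: int = 0) -> "DepthFrame":
        """Build from raw integer millimeters; zeros and NaNs become invalid."""
        raw = np.asarray(raw, dtype=float)
        valid = np.isfinite(raw) & (raw > 0)
        return cls(values=raw / 1000.0, valid_mask=valid, frame_index=frame_index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def align_depth_index(rgb_index: int, clock: FrameClock) -> int:
    """Depth-frame index temporally matched to an RGB frame.

    The two streams free-run at their own rates from a common start, so the
    depth frame covering RGB frame ``t`` is ``floor(t * f_depth / f_rgb)``.
    Identity when the rates are equal.
    """
    if rgb_index < 0:
        raise ValueError("rgb_index must be non-negative")
    return int(math.floor(rgb_index * clock.depth_rate / clock.rgb_rate))


def extract_depth(
    depth: DepthFrame, center: Pixel, window: int = 3
) -> float | None:
    """Robust depth at a pixel: median of the valid values in a local window.

    The window (side ``window``, odd) is centered on ``center`` and clipped
    at the image borders; invalid pixels are discarded before the median so
    they can never bias the estimate.  Returns ``None`` when no valid pixel
    remains — the caller treats that detection as depthless for this frame
    and relies on other frames of the same track.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    h, w = depth.shape
    col = int(round(center.x))
    row = int(round(center.y))
    if not (0 <= col < w and 0 <= row < h):
        raise ValueError(f"window center {center!r} outside {w}x{h} image")
    half = window // 2
    r0, r1 = max(0, row - half), min(h, row + half + 1)
    c0, c1 = max(0, col - half), min(w, col + half + 1)
    patch = depth.values[r0:r1, c0:c1]
    mask = depth.valid_mask[r0:r1, c0:c1]
    vals = patch[mask]
    if vals.size == 0:
        return None
    return float(np.median(vals))


def back_project(p: Pixel, z: float, K: CameraIntrinsics) -> Point3D:
    """Map a pixel and its depth to metric camera coordinates.

    X = (x - cx) * z / fx,  Y = (y - cy) * z / fy,  Z = z.
    Exact algebraic inverse of :func:`project`.
    """
    if not (math.isfinite(z) and z > 0):
        raise ValueError("depth must be finite and positive")
    return Point3D(
        X=(p.x - K.cx) * z / K.fx,
        Y=(p.y - K.cy) * z / K.fy,
        Z=z,
    )


def project(P: Point3D, K: CameraIntrinsics) -> Pixel:
    """Forward pinhole projection of a camera-frame point to pixel coordinates."""
    if not (math.isfinite(P.Z) and P.Z > 0):
        raise ValueError("point must lie in front of the camera (Z > 0)")
    return Pixel(
        x=P.X * K.fx / P.Z + K.cx,
        y=P.Y * K.fy / P.Z + K.cy,
    )


def spacing_3d(a: Point3D, b: Point3D) -> float:
    """3D Euclidean distance in meters between two reconstructed keypoints."""
    if not all(map(math.isfinite, (*a, *b))):
        raise ValueError("coordinates must be finite")
    return math.sqrt((a.X - b.X) ** 2 + (a.Y - b.Y) ** 2 + (a.Z - b.Z) ** 2)
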