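"""RGB-D camera calibration and metric localization of detected targets.

Three linear calibrations take a detected pixel centroid to a metric 3-D
position in the camera (Kinect) frame:

1. an affine pixel map  [x y 1] . B  from RGB-image pixels to depth-image
   pixels (B fitted by least squares from ball correspondences);
2. a linear depth model  distance = 61.5 * depth_index + 0.1046  (metres);
3. linear per-axis pixel-to-metre scales that grow with distance,
   X = (0.001937 d + 0.0001662) px  and  Y = (0.002072 d - 0.000227) py,
   where (px, py) are pixel offsets from the optical centre (W/2, H/2).

A fixed homogeneous transform (pure rotation plus a (1.24, 0, 0.05) m
translation) then maps camera-frame points into the robot frame.  The
module also provides the exact inverse (forward camera model) used to
render synthetic scenes, and serialization of the calibration to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "FrameTransform",
    "MetricPoint",
    "SingularFitError",
    "FrameMismatchError",
    "OutOfViewError",
    "fit_pixel_mapping",
    "map_rgb_to_depth",
    "depth_to_distance",
    "distance_to_depth_index",
    "pixel_to_metric_xy",
    "metric_xy_to_pixel",
    "kinect_to_robot",
    "localize_targets",
]

#: Affine RGB->depth pixel map fitted by the rig calibration (165 ball pairs).
DEFAULT_B = np.array(
    [
        [1.17332, 0.000815],
        [-0.01963, 1.12255],
        [-34.6797, -20.0941],
    ]
)

DEFAULT_IMAGE_SHAPE = (480, 640)  # (H, W)


class SingularFitError(ValueError):
    """Pixel-mapping design matrix is rank deficient."""


class FrameMismatchError(ValueError):
    """A point was supplied in the wrong coordinate frame."""


class OutOfViewError(ValueError):
    """A mapped depth pixel falls outside the depth image."""


@dataclass(frozen=True)
class MetricPoint:
    """A 3-D point in metres, tagged with its coordinate frame."""

    x: float
    y: float
    z: float
    frame: str  # "kinect" or "robot"

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class CalibrationModel:
    """The three linear camera calibrations, shipped with the rig defaults."""

    B: np.ndarray = field(default_factory=lambda: DEFAULT_B.copy())
    depth_slope: float = 61.5  # metres per depth index
    depth_intercept: float = 0.1046  # metres
    x_coeff: tuple[float, float] = (0.001937, 0.0001662)
    y_coeff: tuple[float, float] = (0.002072, -0.000227)

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (3, 2) or not np.isfinite(self.B).all():
            raise ValueError("B must be a finite 3 x 2 matrix")
        if self.depth_slope <= 0:
            raise ValueError("depth_slope must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "B": self.B.tolist(),
            "depth_slope": self.depth_slope,
            "depth_intercept": self.depth_intercept,
            "x_coeff": list(self.x_coeff),
            "y_coeff": list(self.y_coeff),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            B=np.asarray(payload["B"], dtype=float),
            depth_slope=float(payload["depth_slope"]),
            depth_intercept=float(payload["depth_intercept"]),
            x_coeff=tuple(payload["x_coeff"]),
            y_coeff=tuple(payload["y_coeff"]),
        )


@dataclass
class FrameTransform:
    """Homogeneous camera-to-robot transform: b = R a + t."""

    R: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0, 0.0, -1.0], [1.0, 0.0, 0.0], [0.0, -1.0, 0.0]]
        )
    )
    translation: np.ndarray = field(default_factory=lambda: np.array([1.24, 0.0, 0.05]))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise ValueError("R must be orthogonal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-9):
            raise ValueError("R must be a proper rotation (det +1)")

    @property
    def T(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.R
        T[:3, 3] = self.translation
        return T


def fit_pixel_mapping(rgb_coords: np.ndarray, depth_coords: np.ndarray) -> np.ndarray:
    """Least-squares affine map B with [A 1] . B = D.

    ``rgb_coords`` (A) and ``depth_coords`` (D) are n x 2 pixel coordinate
    arrays of the same points seen by the two cameras (n >= 3, non-collinear).
    """
    A = np.asarray(rgb_coords, dtype=float)
    D = np.asarray(depth_coords, dtype=float)
    if A.ndim != 2 or A.shape[1] != 2 or A.shape != D.shape:
        raise ValueError("rgb_coords and depth_coords must be matching n x 2 arrays")
    if len(A) < 3:
        raise ValueError("at least 3 correspondences are required")
    X = np.column_stack([A, np.ones(len(A))])
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError("correspondences are collinear: affine map not identifiable")
    B, *_ = np.linalg.lstsq(X, D, rcond=None)
    return B


def map_rgb_to_depth(pixel: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Map RGB-image pixel(s) (x, y) to depth-image pixel(s) via [x y 1] . B."""
    p = np.asarray(pixel, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    out = np.column_stack([p, np.ones(len(p))]) @ np.asarray(B, dtype=float)
    return out[0] if single else out


def depth_to_distance(depth_index, model: CalibrationModel | None = None):
    """Linear depth calibration: distance (m) = slope * index + intercept."""
    model = model or CalibrationModel()
    return model.depth_slope * np.asarray(depth_index, dtype=float) + model.depth_intercept


def distance_to_depth_index(distance, model: CalibrationModel | None = None):
    """Exact inverse of :func:`depth_to_distance` (used by the forward model)."""
    model = model or CalibrationModel()
    return (np.asarray(distance, dtype=float) - model.depth_intercept) / model.depth_slope


def pixel_to_metric_xy(
    pixel_offset: np.ndarray, distance: float, model: CalibrationModel | None = None
) -> np.ndarray:
    """Convert a pixel offset from the optical centre to metric (X, Y) at ``distance``."""
    model = model or CalibrationModel()
    if distance <= 0:
        raise ValueError("distance must be positive")
    px, py = (float(v) for v in np.asarray(pixel_offset, dtype=float))
    X = (model.x_coeff[0] * distance + model.x_coeff[1]) * px
    Y = (model.y_coeff[0] * distance + model.y_coeff[1]) * py
    return np.array([X, Y])


def metric_xy_to_pixel(
    xy: np.ndarray, distance: float, model: CalibrationModel | None = None
) -> np.ndarray:
    """Exact inverse of :func:`pixel_to_metric_xy` (forward camera model)."""
    model = model or CalibrationModel()
    if distance <= 0:
        raise ValueError("distance must be positive")
    sx = model.x_coeff[0] * distance + model.x_coeff[1]
    sy = model.y_coeff[0] * distance + model.y_coeff[1]
    if sx <= 0 or sy <= 0:
        raise ValueError(f"pixel scale degenerate at distance {distance:.3f} m")
    X, Y = (float(v) for v in np.asarray(xy, dtype=float))
    return np.array([X / sx, Y / sy])


def kinect_to_robot(point: MetricPoint, transform: FrameTransform | None = None) -> MetricPoint:
    """Transform a camera-frame point into the robot frame: b = R a + t."""
    transform = transform or FrameTransform()
    if point.frame != "kinect":
        raise FrameMismatchError(f"expected a kinect-frame point, got frame={point.frame!r}")
    b = transform.R @ point.as_array() + transform.translation
    return MetricPoint(float(b[0]), float(b[1]), float(b[2]), frame="robot")


def _bilinear(grid: np.ndarray, x: float, y: float) -> float:
    """Bilinear sample of ``grid`` at real-valued pixel (x=col, y=row)."""
    h, w = grid.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise OutOfViewError(f"depth pixel ({x:.1f}, {y:.1f}) outside {w} x {h} image")
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    top = grid[y0, x0] * (1 - fx) + grid[y0, x1] * fx
    bot = grid[y1, x0] * (1 - fx) + grid[y1, x1] * fx
    return float(top * (1 - fy) + bot * fy)


def localize_cluster_kinect(
    centroid: tuple[float, float],
    depth_image: np.ndarray,
    model: CalibrationModel | None = None,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
) -> MetricPoint:
    """Metric camera-frame position of one detected centroid.

    The RGB centroid is mapped into the depth image, the depth index is
    bilinearly sampled and converted to a metric distance, and the pixel
    offsets from the optical centre give the metric X, Y at that distance.
    """
    model = model or CalibrationModel()
    cx, cy = centroid
    dx, dy = map_rgb_to_depth(np.array([cx, cy]), model.B)
    index = _bilinear(np.asarray(depth_image, dtype=float), dx, dy)
    distance = float(depth_to_distance(index, model))
    h, w = image_shape
    X, Y = pixel_to_metric_xy((cx - w / 2.0, cy - h / 2.0), distance, model)
    return MetricPoint(float(X), float(Y), distance, frame="kinect")


def localize_targets(
    clusters,
    depth_image: np.ndarray,
    model: CalibrationModel | None = None,
    transform: FrameTransform | None = None,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
):
    """Localize detected clusters as a robot-frame :class:`~sharedreach.shared_control.TargetSet`.

    Each cluster centroid is taken through the three calibrations and the
    camera-to-robot transform; goal joint configurations are solved by
    inverse kinematics when the set is constructed.  An empty cluster list
    yields an empty TargetSet.
    """
    from .shared_control import TargetSet  # local import: avoids a module cycle

    points = [
        kinect_to_robot(
            localize_cluster_kinect(c.centroid, depth_image, model, image_shape), transform
        )
        for c in clusters
    ]
    positions = np.array([[p.x, p.y, p.z] for p in points]).reshape(-1, 3)
    return TargetSet.from_robot_positions(positions)


def targets_to_frame(target_set) -> pd.DataFrame:
    """Tabulate a TargetSet as (target_id, x, y, z, frame='robot') rows."""
    rows = []
    for tid, pos in zip(target_set.ids, target_set.robot_positions):
        rows.append({"target_id": tid, "x": pos[0], "y": pos[1], "z": pos[2], "frame": "robot"})
    return pd.DataFrame(rows, columns=["target_id", "x", "y", "z", "frame"])
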