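"""Synthetic fixtures: rendered RGB-D scenes and decoded-velocity trials.

Two generators make the whole pipeline testable without camera hardware or
EEG recordings:

* :func:`render_scene` inverts the camera calibration exactly (pinhole-free
  linear model) to paint green target disks into an RGB image and their
  depth indices into a depth grid, together with a ground-truth table, so
  detection + localization can be validated round-trip.

* :func:`generate_trials` emulates noisy decoded hand velocities: each
  trial's ideal velocity points from the current ideal position to the
  trial's target, and the decoded vector is that velocity rotated by a
  random axis-angle perturbation and scaled by multiplicative magnitude
  noise.  The ensemble mirrors the evaluation protocol of 4 reaching
  directions with 30 trials each (~0.4 m reaches).

Everything is reproducible bit-for-bit from the spec seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal
from .kinematics import JointConfig, inverse
from .shared_control import DecodedTrajectory, TargetSet

__all__ = [
    "SceneSpec",
    "TrajectorySpec",
    "SceneSpecError",
    "render_scene",
    "sample_scene_positions",
    "generate_trials",
    "default_target_layout",
]

#: Target ball radius in metres (7 cm diameter green balls).
DEFAULT_DISK_RADIUS = 0.035

_GREEN = (40, 200, 40)
_BACKGROUND_DISTANCE = 2.5  # metres behind the targets


class SceneSpecError(ValueError):
    """Scene specification violates its geometric constraints."""


@dataclass
class SceneSpec:
    """A synthetic workspace scene of 2-4 green targets in the camera frame.

    Pairwise target separations must lie within [0.15, 0.35] m, matching the
    detection-validation protocol; targets must project fully inside the
    camera frustum.
    """

    target_positions: np.ndarray  # (n, 3) kinect-frame metres
    disk_radius: float = DEFAULT_DISK_RADIUS
    background: tuple[int, int, int] = (120, 120, 120)
    image_shape: tuple[int, int] = cal.DEFAULT_IMAGE_SHAPE

    def __post_init__(self) -> None:
        self.target_positions = np.asarray(self.target_positions, dtype=float).reshape(-1, 3)
        if self.disk_radius <= 0:
            raise SceneSpecError("disk_radius must be positive")
        n = len(self.target_positions)
        for i in range(n):
            for j in range(i + 1, n):
                sep = float(
                    np.linalg.norm(self.target_positions[i] - self.target_positions[j])
                )
                if not 0.15 - 1e-9 <= sep <= 0.35 + 1e-9:
                    raise SceneSpecError(
                        f"targets {i} and {j} separated by {sep:.3f} m; "
                        "separations must lie in [0.15, 0.35] m"
                    )

    @property
    def n_targets(self) -> int:
        return len(self.target_positions)


def sample_scene_positions(
    n_targets: int,
    rng: np.random.Generator,
    depth_range: tuple[float, float] = (0.95, 1.1),
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Draw camera-frame target positions with all pairwise separations in [0.15, 0.35] m.

    Positions are rejection-sampled inside a frustum-safe box (|X| <= 0.30 m,
    |Y| <= 0.18 m at ~1 m depth).  Targets sit on flexible supports at
    similar depths and are separated laterally, so the separation constraint
    is enforced in the image (X, Y) plane — at least 0.15 m apart laterally —
    while the full 3-D separation stays within 0.35 m.
    """
    if not 1 <= n_targets <= 4:
        raise SceneSpecError("n_targets must be between 1 and 4")
    lo = np.array([-0.30, -0.18, depth_range[0]])
    hi = np.array([0.30, 0.18, depth_range[1]])
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_targets:
        if attempts > max_attempts:
            raise SceneSpecError("could not place targets within separation constraints")
        attempts += 1
        p = rng.uniform(lo, hi)
        ok = all(
            0.15 <= float(np.linalg.norm(p[:2] - q[:2]))
            and float(np.linalg.norm(p - q)) <= 0.35
            for q in positions
        )
        if ok:
            positions.append(p)
    return np.asarray(positions)


def _project(spec: SceneSpec, model: cal.CalibrationModel):
    """Pixel centres and per-axis pixel radii of each target disk."""
    h, w = spec.image_shape
    out = []
    for X, Y, Z in spec.target_positions:
        px, py = cal.metric_xy_to_pixel((X, Y), Z, model)
        sx = model.x_coeff[0] * Z + model.x_coeff[1]
        sy = model.y_coeff[0] * Z + model.y_coeff[1]
        out.append((px + w / 2.0, py + h / 2.0, spec.disk_radius / sx, spec.disk_radius / sy))
    return out


def render_scene(
    spec: SceneSpec, model: cal.CalibrationModel | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render (rgb_image, depth_index_grid, ground_truth_table) for a scene.

    The RGB image carries green elliptical disks (projected balls) on a
    uniform background; the depth grid carries each target's exact depth
    index at the pixels the RGB->depth map sends its disk to, over a distant
    uniform background.  The ground-truth table lists exact camera-frame
    positions and projected pixel centres.
    """
    model = model or cal.CalibrationModel()
    h, w = spec.image_shape
    disks = _project(spec, model)

    for i in range(len(disks)):
        for j in range(i + 1, len(disks)):
            dx = disks[i][0] - disks[j][0]
            dy = disks[i][1] - disks[j][1]
            r_i = max(disks[i][2], disks[i][3])
            r_j = max(disks[j][2], disks[j][3])
            if np.hypot(dx, dy) <= r_i + r_j + 2:
                raise SceneSpecError(f"target disks {i} and {j} overlap in the image")

    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[:] = np.asarray(spec.background, dtype=np.uint8)
    depth = np.full(
        (h, w), cal.distance_to_depth_index(_BACKGROUND_DISTANCE, model), dtype=float
    )

    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for tid, ((X, Y, Z), (px, py, rx, ry)) in enumerate(
        zip(spec.target_positions, disks), start=1
    ):
        if not (rx + 2 <= px <= w - rx - 3 and ry + 2 <= py <= h - ry - 3):
            raise SceneSpecError(f"target {tid} does not project fully inside the image")
        mask = ((xx - px) / rx) ** 2 + ((yy - py) / ry) ** 2 <= 1.0
        rgb[mask] = _GREEN

        dxp, dyp = cal.map_rgb_to_depth(np.array([px, py]), model.B)
        if not (0 <= dxp <= w - 1 and 0 <= dyp <= h - 1):
            raise SceneSpecError(f"target {tid} maps outside the depth image")
        dr = max(rx, ry) * 1.3 + 3.0
        dmask = (xx - dxp) ** 2 + (yy - dyp) ** 2 <= dr * dr
        depth[dmask] = cal.distance_to_depth_index(Z, model)
        rows.append(
            {"target_id": tid, "x": X, "y": Y, "z": Z, "pixel_x": px, "pixel_y": py}
        )

    truth = pd.DataFrame(rows, columns=["target_id", "x", "y", "z", "pixel_x", "pixel_y"])
    return rgb, depth, truth


@dataclass
class TrajectorySpec:
    """Parameters of the decoded-velocity ensemble.

    Defaults emulate the evaluation dataset: 4 reaching directions, 30
    trials per direction, 50 steps of 8 mm (a ~0.4 m noise-free reach).
    ``angular_noise_sd`` (rad) and ``magnitude_noise_sd`` (fractional) set
    the decoded-velocity degradation; ``ar1`` optionally correlates the
    angular perturbation over time (off by default).
    """

    n_directions: int = 4
    trials_per_direction: int = 30
    n_steps: int = 50
    base_step: float = 0.008
    angular_noise_sd: float = 0.7
    magnitude_noise_sd: float = 0.25
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 1 or self.trials_per_direction < 1 or self.n_steps < 1:
            raise ValueError("counts must be positive")
        if self.base_step <= 0:
            raise ValueError("base_step must be positive")
        if self.angular_noise_sd < 0 or self.magnitude_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must lie in [0, 1)")


def _rotate(v: np.ndarray, rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of ``v`` by the axis-angle vector ``rotvec``."""
    angle = float(np.linalg.norm(rotvec))
    if angle == 0.0:
        return v
    k = rotvec / angle
    return (
        v * np.cos(angle)
        + np.cross(k, v) * np.sin(angle)
        + k * float(np.dot(k, v)) * (1.0 - np.cos(angle))
    )


def generate_trials(
    spec: TrajectorySpec, targets: TargetSet, start: np.ndarray
) -> list[DecodedTrajectory]:
    """Generate the decoded-velocity ensemble for a target layout.

    Direction d (1-based) reaches for the d-th target.  The ideal velocity
    at each step points from the current ideal position to that target with
    length ``base_step`` (shortened on the final approach); the decoded
    velocity is the ideal one rotated by a random axis-angle perturbation
    (angle ~ N(0, angular_noise_sd), axis uniform) and scaled by
    (1 + N(0, magnitude_noise_sd)).  Fully determined by ``spec.seed``.
    """
    if spec.n_directions > len(targets):
        raise ValueError("need at least one target per reaching direction")
    rng = np.random.default_rng(spec.seed)
    start = np.asarray(start, dtype=float)
    trials: list[DecodedTrajectory] = []
    for d in range(1, spec.n_directions + 1):
        target = targets[targets.ids[d - 1]]
        for _ in range(spec.trials_per_direction):
            current = start.copy()
            rotvec = np.zeros(3)
            vels = np.zeros((spec.n_steps, 3))
            for k in range(spec.n_steps):
                to_target = target.position - current
                dist = float(np.linalg.norm(to_target))
                if dist > 0.0:
                    v_true = to_target * (min(spec.base_step, dist) / dist)
                else:
                    v_true = np.zeros(3)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                innovation_sd = spec.angular_noise_sd * np.sqrt(1.0 - spec.ar1**2)
                rotvec = spec.ar1 * rotvec + axis * rng.normal(0.0, innovation_sd)
                scale = 1.0 + rng.normal(0.0, spec.magnitude_noise_sd)
                vels[k] = _rotate(v_true, rotvec) * scale
                current = current + v_true
            trials.append(
                DecodedTrajectory(
                    velocities=vels,
                    true_target_id=target.id,
                    direction_label=d,
                )
            )
    return trials


def default_target_layout() -> tuple[TargetSet, JointConfig]:
    """The default 4-target evaluation layout and start configuration.

    Four reachable frame-0 targets roughly 0.36-0.40 m from the start
    position (0.40, 0, -0.15) m, spanning four distinct reaching directions
    (left/right and low/high), comparable to a tabletop workspace of green
    balls in front of the arm.
    """
    positions = np.array(
        [
            [0.50, 0.22, 0.12],
            [0.50, -0.22, 0.12],
            [0.50, 0.10, 0.22],
            [0.50, -0.10, 0.22],
        ]
    )
    targets = TargetSet.from_positions(positions)
    start = inverse(np.array([0.40, 0.0, -0.15]))
    return targets, start
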