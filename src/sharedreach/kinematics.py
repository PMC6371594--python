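"""Forward and inverse kinematics of the 3-DOF anthropomorphic positioning arm.

The assistive robot's reaching motion is generated with the first three
joints of an anthropomorphic arm (shoulder yaw, shoulder pitch, elbow),
described by Denavit-Hartenberg parameters a = (0, a2, a3),
alpha = (pi/2, 0, 0), d = (0, 0, 0) with link lengths a2 = 0.41 m and
a3 = 0.44 m.  The end-effector position in frame 0 is

    p = ( c1 (a2 c2 + a3 c23),  s1 (a2 c2 + a3 c23),  a2 s2 + a3 s23 )

where c1 = cos(theta1), s23 = sin(theta2 + theta3), etc.  The closed-form
inverse uses the law of cosines for the elbow angle and a two-argument
arctangent for the shoulder pitch, with both elbow branches available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DHTable",
    "JointConfig",
    "EndEffectorPose",
    "WorkspaceError",
    "ARM_BASE_OFFSET",
    "forward",
    "inverse",
    "normalize_angle",
]

#: Offset (metres) of the robot-frame origin from the kinematic frame 0
#: (centre of joint 1): 0.2 m along x and z.  Points expressed in the robot
#: frame are converted to frame 0 by adding this vector.
ARM_BASE_OFFSET = np.array([0.2, 0.0, 0.2])

_EPS_REACH = 1e-12


class WorkspaceError(ValueError):
    """Requested end-effector position lies outside the reachable annulus."""


@dataclass(frozen=True)
class DHTable:
    """Denavit-Hartenberg link lengths of the positioning subchain (metres)."""

    a2: float = 0.41
    a3: float = 0.44

    def __post_init__(self) -> None:
        if not (self.a2 > 0 and self.a3 > 0):
            raise ValueError("link lengths a2, a3 must be positive")

    @property
    def r_min(self) -> float:
        return abs(self.a2 - self.a3)

    @property
    def r_max(self) -> float:
        return self.a2 + self.a3


DEFAULT_DH = DHTable()


def normalize_angle(theta: float) -> float:
    """Wrap an angle to the half-open interval (-pi, pi]."""
    t = math.atan2(math.sin(theta), math.cos(theta))
    return math.pi if t <= -math.pi else t


@dataclass(frozen=True)
class JointConfig:
    """Joint angle triple (theta1, theta2, theta3) in radians, each in (-pi, pi]."""

    theta: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.theta) != 3:
            raise ValueError("JointConfig requires exactly three joint angles")
        object.__setattr__(self, "theta", tuple(float(t) for t in self.theta))

    def normalized(self) -> "JointConfig":
        return JointConfig(tuple(normalize_angle(t) for t in self.theta))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.theta, dtype=float)


@dataclass(frozen=True)
class EndEffectorPose:
    """End-effector position (metres, frame 0) and orientation."""

    position: np.ndarray
    rotation: np.ndarray


def _fk_position(t1: float, t2: float, t3: float, a2: float, a3: float):
    c1, s1 = math.cos(t1), math.sin(t1)
    c2, s2 = math.cos(t2), math.sin(t2)
    c23, s23 = math.cos(t2 + t3), math.sin(t2 + t3)
    reach = a2 * c2 + a3 * c23
    return c1 * reach, s1 * reach, a2 * s2 + a3 * s23


def forward(q: JointConfig, dh: DHTable = DEFAULT_DH) -> EndEffectorPose:
    """Forward kinematics: joint angles to end-effector pose in frame 0."""
    t1, t2, t3 = q.theta
    c1, s1 = math.cos(t1), math.sin(t1)
    c23, s23 = math.cos(t2 + t3), math.sin(t2 + t3)
    position = np.array(_fk_position(t1, t2, t3, dh.a2, dh.a3))
    rotation = np.array(
        [
            [c1 * c23, -c1 * s23, s1],
            [s1 * c23, -s1 * s23, -c1],
            [s23, c23, 0.0],
        ]
    )
    return EndEffectorPose(position=position, rotation=rotation)


def _ik(px: float, py: float, pz: float, a2: float, a3: float, elbow: int):
    """Closed-form IK returning (theta1, theta2, theta3); raises WorkspaceError."""
    r2 = px * px + py * py + pz * pz
    r = math.sqrt(r2)
    r_min, r_max = abs(a2 - a3), a2 + a3
    if r > r_max + _EPS_REACH or r < r_min - _EPS_REACH:
        raise WorkspaceError(
            f"position with radius {r:.6f} m outside reachable annulus "
            f"[{r_min:.3f}, {r_max:.3f}] m"
        )
    c3 = (r2 - a2 * a2 - a3 * a3) / (2.0 * a2 * a3)
    c3 = min(1.0, max(-1.0, c3))
    s3 = elbow * math.sqrt(max(0.0, 1.0 - c3 * c3))
    theta3 = math.atan2(s3, c3)
    rho = math.hypot(px, py)
    theta2 = math.atan2(
        (a2 + a3 * c3) * pz - a3 * s3 * rho,
        (a2 + a3 * c3) * rho + a3 * s3 * pz,
    )
    # theta1 is undefined on the vertical axis (rho = 0); by convention it is 0
    # there, which makes the singular vertical reach return (0, pi/2, 0).
    theta1 = math.atan2(py, px)
    return theta1, theta2, theta3


def inverse(
    position: np.ndarray,
    dh: DHTable = DEFAULT_DH,
    elbow: str = "up",
) -> JointConfig:
    """Inverse kinematics: end-effector position (frame 0) to joint angles.

    Parameters
    ----------
    position
        Target (x, y, z) in metres, frame 0.
    elbow
        Branch flag: ``"up"`` takes sin(theta3) >= 0, ``"down"`` the mirror
        branch.  Both satisfy forward(inverse(p)) == p on the open workspace.

    Raises
    ------
    WorkspaceError
        If ``position`` lies outside the annulus |a2-a3| <= ||p|| <= a2+a3.
    """
    if elbow not in ("up", "down"):
        raise ValueError("elbow must be 'up' or 'down'")
    px, py, pz = (float(v) for v in np.asarray(position, dtype=float))
    sign = 1 if elbow == "up" else -1
    t1, t2, t3 = _ik(px, py, pz, dh.a2, dh.a3, sign)
    return JointConfig((normalize_angle(t1), normalize_angle(t2), normalize_angle(t3)))
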