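"""Artificial-potential shared control for BMI reaching.

The user's decoded hand velocity (a noisy 3-D vector stream predicted from
neural signals) is too inaccurate on its own to drive a robotic arm to a
target.  Shared control infers, at every waypoint, which candidate target
the user intends — the one whose direction from the current end-effector
position makes the smallest angle with the decoded velocity — and forms an
attractive artificial potential toward it.  With unit stiffness on the
intended target and zero on the others, the attractive joint-space force is
f_t = q_goal - q, and the induced ideal Cartesian step

    dx_ideal = x_e(q + f_t) - x_e(q)  =  target_position - current_position.

The ideal direction, rescaled to the decoded speed, is blended with the
decoded vector:

    dx_k = 1.5 * [ alpha * ||dx_dec|| * unit(dx_ideal) + (1 - alpha) * dx_dec ]

and an inertia term smooths consecutive compensation vectors:

    s_k = beta * dx_k + (1 - beta) * dx_{k-1}.

alpha in [0, 1] weights machine compensation against user volition
(alpha = 1 is observation-based training); beta in [0, 1] suppresses sudden
direction changes.  A step is only taken when the decoded velocity points
away from the motion origin and within 90 degrees of the intended target
direction; otherwise the arm holds its position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import (
    ARM_BASE_OFFSET,
    DEFAULT_DH,
    DHTable,
    JointConfig,
    _fk_position,
    _ik,
    forward,
    inverse,
)

__all__ = [
    "Target",
    "TargetSet",
    "SharedControlParams",
    "ControlState",
    "DecodedTrajectory",
    "TrialRun",
    "infer_intended_target",
    "attract",
    "blend",
    "step",
    "run_trial",
]

_BOUNDARY_MARGIN = 1e-9


@dataclass(frozen=True)
class Target:
    """One candidate target: id, frame-0 position (m), and IK goal configuration."""

    id: int
    position: np.ndarray
    goal_config: JointConfig


class TargetSet:
    """Candidate targets with reachable positions and their goal configurations.

    Positions are stored in the arm's kinematic frame 0; ``from_robot_positions``
    accepts robot-frame coordinates and applies the fixed base offset.
    """

    def __init__(
        self,
        positions: np.ndarray,
        ids: list[int] | None = None,
        dh: DHTable = DEFAULT_DH,
        elbow: str = "up",
    ):
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        ids = list(range(1, len(positions) + 1)) if ids is None else list(ids)
        if len(ids) != len(positions):
            raise ValueError("ids and positions length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("target ids must be unique")
        self.dh = dh
        self.elbow = elbow
        self.targets: list[Target] = [
            Target(id=i, position=p, goal_config=inverse(p, dh, elbow))
            for i, p in zip(ids, positions)
        ]
        self._by_id = {t.id: t for t in self.targets}
        self.positions = positions
        self.ids = ids

    @classmethod
    def from_positions(cls, positions, ids=None, **kw) -> "TargetSet":
        return cls(positions, ids, **kw)

    @classmethod
    def from_robot_positions(cls, positions, ids=None, **kw) -> "TargetSet":
        """Build from robot-frame coordinates (frame 0 = robot + base offset)."""
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        return cls(positions + ARM_BASE_OFFSET, ids, **kw)

    @property
    def robot_positions(self) -> np.ndarray:
        return self.positions - ARM_BASE_OFFSET

    def __len__(self) -> int:
        return len(self.targets)

    def __getitem__(self, target_id: int) -> Target:
        try:
            return self._by_id[target_id]
        except KeyError:
            raise KeyError(f"no target with id {target_id}") from None


@dataclass(frozen=True)
class SharedControlParams:
    """Blending parameters and loop settings.

    alpha
        Weight of the vision-derived ideal direction (0 = decoded velocity
        only, 1 = full machine compensation / observation-based training).
    beta
        Inertia weight on the current compensation vector (1 = no inertia).
    step_scale
        Overall gain applied to each compensation vector (1.5).
    reach_tolerance
        Trial stops once the end-effector is within this distance of any
        target (0.02 m: a 1-2 cm deviation is tolerable given gripper and
        target size).
    """

    alpha: float
    beta: float
    step_scale: float = 1.5
    reach_tolerance: float = 0.02
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")


@dataclass
class ControlState:
    """Controller state at waypoint k."""

    current_config: JointConfig
    current_position: np.ndarray
    previous_step: np.ndarray | None = None
    step_index: int = 0
    intended_target_id: int | None = None
    clamped: bool = False  # last step was truncated at the workspace boundary

    @classmethod
    def from_config(cls, q: JointConfig, dh: DHTable = DEFAULT_DH) -> "ControlState":
        return cls(current_config=q, current_position=forward(q, dh).position)


@dataclass(frozen=True)
class DecodedTrajectory:
    """One trial's decoded hand-velocity stream with its ground-truth label."""

    velocities: np.ndarray  # (n_steps, 3), metres per step
    true_target_id: int
    direction_label: int

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        if len(v) == 0:
            raise ValueError("trajectory must contain at least one velocity")
        if not np.isfinite(v).all():
            raise ValueError("velocities must be finite")
        object.__setattr__(self, "velocities", v)


@dataclass
class TrialRun:
    """Waypoint sequence and per-step flags produced by :func:`run_trial`."""

    waypoints: np.ndarray  # (n+1, 3) frame-0 positions, start included
    intended_ids: list[int | None]
    gated: list[bool]  # True where the gate failed and the arm held position
    clamped: list[bool]
    reached: bool
    reached_step: int | None


def infer_intended_target(
    velocity: np.ndarray, position: np.ndarray, targets: TargetSet
) -> int | None:
    """Id of the target whose direction from ``position`` best matches ``velocity``.

    The intended target minimizes the angle between the decoded velocity and
    the vector from the current position to the target; ties go to the
    lowest id.  A zero velocity carries no intent and returns None; a target
    coincident with the current position is returned as already reached.
    """
    v = np.asarray(velocity, dtype=float)
    vnorm = float(np.linalg.norm(v))
    if vnorm == 0.0:
        return None
    best_id, best_cos = None, -2.0
    for t in targets.targets:
        d = t.position - position
        dn = float(np.linalg.norm(d))
        if dn == 0.0:
            return t.id
        c = float(np.dot(v, d)) / (vnorm * dn)
        if c > best_cos or (c == best_cos and (best_id is None or t.id < best_id)):
            best_cos, best_id = c, t.id
    return best_id


def attract(state: ControlState, intended: int, targets: TargetSet) -> np.ndarray:
    """Ideal Cartesian step induced by the attractive potential of the intended target.

    With stiffness 1 on the intended target and 0 elsewhere, the joint-space
    force is f_t = q_goal - q_k, and the returned vector is
    x_e(q_k + f_t) - x_e(q_k), which equals target_position - current_position.
    """
    target = targets[intended]
    q = state.current_config.theta
    qg = target.goal_config.theta
    f_t = (qg[0] - q[0], qg[1] - q[1], qg[2] - q[2])
    dh = targets.dh
    goal_pos = _fk_position(
        q[0] + f_t[0], q[1] + f_t[1], q[2] + f_t[2], dh.a2, dh.a3
    )
    return np.asarray(goal_pos) - state.current_position


def blend(
    decoded: np.ndarray, ideal: np.ndarray, alpha: float, step_scale: float = 1.5
) -> np.ndarray:
    """Blend the decoded velocity with the ideal direction rescaled to its speed.

    Returns step_scale * [alpha * ||decoded|| * unit(ideal) + (1-alpha) * decoded].
    The result's norm never exceeds step_scale * ||decoded||, with equality
    at alpha in {0, 1}.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    decoded = np.asarray(decoded, dtype=float)
    ideal = np.asarray(ideal, dtype=float)
    if alpha == 0.0:
        return step_scale * decoded
    ideal_norm = float(np.linalg.norm(ideal))
    if ideal_norm == 0.0:
        raise ValueError("ideal direction must be nonzero when alpha > 0")
    speed = float(np.linalg.norm(decoded))
    return step_scale * (alpha * speed * ideal / ideal_norm + (1.0 - alpha) * decoded)


def _clamp_to_workspace(
    position: np.ndarray, displacement: np.ndarray, dh: DHTable
) -> tuple[np.ndarray, bool]:
    """Truncate a displacement at the reachable annulus boundary.

    Returns the feasible new position and whether clamping occurred.  The
    step is shortened along its own direction so that the trial can continue.
    """
    new = position + displacement
    r = float(np.linalg.norm(new))
    r_lo, r_hi = dh.r_min + _BOUNDARY_MARGIN, dh.r_max - _BOUNDARY_MARGIN
    if r_lo <= r <= r_hi:
        return new, False
    bound = r_hi if r > r_hi else r_lo
    a = float(np.dot(displacement, displacement))
    if a == 0.0:
        return position, True
    b = 2.0 * float(np.dot(position, displacement))
    c = float(np.dot(position, position)) - bound * bound
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return position, True
    sq = math.sqrt(disc)
    candidates = [t for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)) if 0.0 <= t <= 1.0]
    if not candidates:
        return position, True
    t = max(candidates) if r > r_hi else min(candidates)
    return position + t * displacement, True


def step(state: ControlState, blended: np.ndarray, beta: float, dh: DHTable = DEFAULT_DH) -> ControlState:
    """Advance one waypoint, applying inertia s_k = beta dx_k + (1-beta) dx_{k-1}.

    The very first step has no predecessor and is applied unblended.  A step
    that would leave the reachable workspace is clamped at the boundary.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    blended = np.asarray(blended, dtype=float)
    if state.previous_step is None:
        s = blended
    else:
        s = beta * blended + (1.0 - beta) * state.previous_step
    new_position, clamped = _clamp_to_workspace(state.current_position, s, dh)
    t1, t2, t3 = _ik(new_position[0], new_position[1], new_position[2], dh.a2, dh.a3, 1)
    return ControlState(
        current_config=JointConfig((t1, t2, t3)).normalized(),
        current_position=new_position,
        previous_step=blended,
        step_index=state.step_index + 1,
        intended_target_id=state.intended_target_id,
        clamped=clamped,
    )


def run_trial(
    trajectory: DecodedTrajectory,
    targets: TargetSet,
    params: SharedControlParams,
    start: JointConfig,
) -> TrialRun:
    """Run the full shared-control loop over one decoded-velocity stream.

    Per decoded velocity: infer the intended target; if the velocity points
    away from the motion origin and within 90 degrees of the intended-target
    direction, blend, apply inertia and move; otherwise hold position.  The
    trial ends early once any target is within ``params.reach_tolerance``.
    One waypoint is emitted per velocity (plus the start), so the output
    stays time-aligned with the input stream.
    """
    dh = targets.dh
    state = ControlState.from_config(start, dh)
    start_position = state.current_position.copy()
    waypoints = [start_position.copy()]
    intended_ids: list[int | None] = []
    gated: list[bool] = []
    clamped_flags: list[bool] = []
    reached = False
    reached_step: int | None = None

    target_positions = targets.positions
    tol = params.reach_tolerance
    n_steps = len(trajectory.velocities)
    if params.max_steps is not None:
        n_steps = min(n_steps, params.max_steps)

    for k in range(n_steps):
        v = trajectory.velocities[k]
        intended = infer_intended_target(v, state.current_position, targets)
        state.intended_target_id = intended
        intended_ids.append(intended)

        move = intended is not None
        if move:
            outward = float(np.dot(v, state.current_position - start_position)) >= 0.0
            toward = float(
                np.dot(v, targets[intended].position - state.current_position)
            ) > 0.0
            move = outward and toward
        if move:
            ideal = attract(state, intended, targets)
            if params.alpha > 0.0 and float(np.linalg.norm(ideal)) == 0.0:
                move = False  # sitting exactly on the intended target
        if move:
            dx = blend(v, ideal, params.alpha, params.step_scale)
            state = step(state, dx, params.beta, dh)
            clamped_flags.append(state.clamped)
            gated.append(False)
        else:
            gated.append(True)
            clamped_flags.append(False)
        waypoints.append(state.current_position.copy())

        dists = np.linalg.norm(target_positions - state.current_position, axis=1)
        if dists.min() <= tol:
            reached = True
            reached_step = k + 1
            break

    return TrialRun(
        waypoints=np.asarray(waypoints),
        intended_ids=intended_ids,
        gated=gated,
        clamped=clamped_flags,
        reached=reached,
        reached_step=reached_step,
    )
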