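"""Shared control: intent inference, attraction, blending, inertia, trial loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sharedreach import shared_control as sc
from sharedreach.kinematics import JointConfig, forward, inverse


@pytest.fixture
def simple_targets():
    # Two orthogonal targets reachable by the arm
    return sc.TargetSet.from_positions([[0.6, 0.0, 0.0], [0.0, 0.6, 0.0]])


class TestInferIntendedTarget:
    def test_smaller_angle_wins(self, simple_targets):
        tid = sc.infer_intended_target(
            np.array([0.9, 0.1, 0.0]), np.zeros(3), simple_targets
        )
        assert tid == 1

    def test_exact_bisection_breaks_to_lowest_id(self, simple_targets):
        tid = sc.infer_intended_target(
            np.array([1.0, 1.0, 0.0]), np.zeros(3), simple_targets
        )
        assert tid == 1

    def test_zero_velocity_returns_none(self, simple_targets):
        assert sc.infer_intended_target(np.zeros(3), np.zeros(3), simple_targets) is None

    def test_coincident_target_reported_reached(self, simple_targets):
        tid = sc.infer_intended_target(
            np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.6, 0.0]), simple_targets
        )
        assert tid == 2

    def test_matches_bruteforce_angle_oracle(self, layout):
        targets, _ = layout
        rng = np.random.default_rng(31)
        position = np.array([0.4, 0.0, -0.15])
        dirs = targets.positions - position
        for _ in range(10_000):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            angles = [
                math.acos(
                    np.clip(np.dot(v, d) / (np.linalg.norm(d)), -1.0, 1.0)
                )
                for d in dirs
            ]
            expected = targets.ids[int(np.argmin(angles))]
            assert sc.infer_intended_target(v, position, targets) == expected


class TestAttract:
    def test_quarter_turn_example(self):
        targets = sc.TargetSet.from_positions([[0.0, 0.85, 0.0]])
        state = sc.ControlState.from_config(JointConfig((0.0, 0.0, 0.0)))
        dx = sc.attract(state, 1, targets)
        assert np.allclose(dx, [-0.85, 0.85, 0.0], atol=1e-12)

    def test_coincident_target_zero_vector(self):
        targets = sc.TargetSet.from_positions([[0.6, 0.1, 0.0]])
        state = sc.ControlState.from_config(targets[1].goal_config)
        dx = sc.attract(state, 1, targets)
        assert np.linalg.norm(dx) < 1e-12

    def test_identity_over_random_pairs(self):
        # With unit stiffness on the intended target, the induced step is
        # exactly target - position, independent of the current config.
        rng = np.random.default_rng(17)
        for _ in range(1000):
            u = rng.normal(size=3)
            target = u / np.linalg.norm(u) * rng.uniform(0.1, 0.8)
            q = JointConfig(rng.uniform(-math.pi, math.pi, size=3))
            targets = sc.TargetSet.from_positions([target])
            state = sc.ControlState.from_config(q)
            dx = sc.attract(state, 1, targets)
            err = np.linalg.norm(dx - (target - state.current_position))
            assert err < 1e-12

    def test_unknown_target_id(self, simple_targets):
        state = sc.ControlState.from_config(JointConfig((0, 0.2, 0.3)))
        with pytest.raises(KeyError):
            sc.attract(state, 99, simple_targets)


class TestBlend:
    def test_alpha_zero_passthrough(self):
        dec = np.array([0.1, -0.2, 0.05])
        out = sc.blend(dec, np.array([1.0, 0, 0]), alpha=0.0)
        assert np.allclose(out, 1.5 * dec, atol=0)

    def test_alpha_one_rescaled_ideal(self):
        dec = np.array([0.0, 0.2, 0.0])
        ideal = np.array([3.0, 0.0, 0.0])
        out = sc.blend(dec, ideal, alpha=1.0)
        assert np.allclose(out, [1.5 * 0.2, 0.0, 0.0], atol=1e-15)

    def test_midpoint_example(self):
        out = sc.blend(np.array([1.0, 0, 0]), np.array([0.0, 2.0, 0]), alpha=0.5)
        assert np.allclose(out, [0.75, 0.75, 0.0], atol=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            sc.blend(np.ones(3), np.ones(3), alpha=1.2)

    def test_zero_ideal_rejected_when_alpha_positive(self):
        with pytest.raises(ValueError):
            sc.blend(np.ones(3), np.zeros(3), alpha=0.5)

    def test_volition_preserved_orthogonal(self):
        # decoded orthogonal to ideal: the blended step keeps a decoded component
        dec = np.array([0.1, 0.0, 0.0])
        ideal = np.array([0.0, 1.0, 0.0])
        out = sc.blend(dec, ideal, alpha=0.7)
        assert np.dot(out, dec) > 0


@settings(derandomize=True, max_examples=300)
@given(
    dec=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    ideal=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    alpha=st.floats(0, 1),
)
def test_blend_norm_and_plane_properties(dec, ideal, alpha):
    dec = np.array(dec)
    ideal = np.array(ideal)
    if np.linalg.norm(ideal) < 1e-6:
        ideal = np.array([1.0, 0.0, 0.0])
    out = sc.blend(dec, ideal, alpha)
    # norm contract ||dx_k|| <= 1.5 ||dx_dec||
    assert np.linalg.norm(out) <= 1.5 * np.linalg.norm(dec) + 1e-9
    # blended vector lies in span{decoded, ideal}
    normal = np.cross(dec, ideal)
    if np.linalg.norm(normal) > 1e-9:
        assert abs(np.dot(out, normal)) / np.linalg.norm(normal) < 1e-9


class TestStep:
    def test_beta_one_no_inertia(self):
        state = sc.ControlState.from_config(JointConfig((0.0, 0.3, 1.8)))
        state.previous_step = np.array([0.05, 0.0, 0.0])
        dx = np.array([0.0, 0.02, 0.0])
        new = sc.step(state, dx, beta=1.0)
        assert np.allclose(new.current_position - state.current_position, dx)

    def test_beta_zero_pure_inertia(self):
        state = sc.ControlState.from_config(JointConfig((0.0, 0.3, 1.8)))
        prev = np.array([0.02, 0.01, 0.0])
        state.previous_step = prev
        new = sc.step(state, np.array([0.0, 0.0, 0.03]), beta=0.0)
        assert np.allclose(new.current_position - state.current_position, prev)

    def test_first_step_applied_unblended(self):
        state = sc.ControlState.from_config(JointConfig((0.0, 0.3, 1.8)))
        dx = np.array([0.01, 0.0, 0.01])
        new = sc.step(state, dx, beta=0.2)
        assert np.allclose(new.current_position - state.current_position, dx)

    def test_constant_stream_fixed_point(self):
        # With a constant compensation vector the displacement is constant
        # for any beta.
        for beta in (0.0, 0.3, 0.8, 1.0):
            state = sc.ControlState.from_config(JointConfig((0.0, 0.3, 1.8)))
            dx = np.array([0.004, 0.001, 0.002])
            positions = [state.current_position.copy()]
            for _ in range(5):
                state = sc.step(state, dx, beta=beta)
                positions.append(state.current_position.copy())
            steps = np.diff(np.asarray(positions), axis=0)
            assert np.allclose(steps, dx, atol=1e-12)

    def test_config_tracks_position(self):
        state = sc.ControlState.from_config(JointConfig((0.1, 0.3, 0.4)))
        new = sc.step(state, np.array([0.01, 0.02, -0.01]), beta=1.0)
        assert np.allclose(forward(new.current_config).position, new.current_position, atol=1e-9)

    def test_workspace_violation_clamped(self):
        start = inverse(np.array([0.84, 0.0, 0.0]))
        state = sc.ControlState.from_config(start)
        new = sc.step(state, np.array([0.2, 0.0, 0.0]), beta=1.0)
        assert new.clamped
        assert np.linalg.norm(new.current_position) <= 0.85


class TestRunTrial:
    def test_zero_velocity_holds_position(self, layout):
        targets, start = layout
        traj = sc.DecodedTrajectory(
            velocities=np.zeros((10, 3)), true_target_id=1, direction_label=1
        )
        run = sc.run_trial(traj, targets, sc.SharedControlParams(0.6, 0.6), start)
        assert len(run.waypoints) == 11
        assert np.allclose(run.waypoints, run.waypoints[0])
        assert all(run.gated)

    def test_alpha_zero_integrates_scaled_decoded(self, layout):
        targets, start = layout
        start_pos = forward(start).position
        direction = targets[1].position - start_pos
        direction /= np.linalg.norm(direction)
        vels = np.tile(direction * 0.01, (10, 1))
        traj = sc.DecodedTrajectory(velocities=vels, true_target_id=1, direction_label=1)
        params = sc.SharedControlParams(alpha=0.0, beta=1.0, reach_tolerance=1e-9)
        run = sc.run_trial(traj, targets, params, start)
        expected = np.vstack([start_pos, start_pos + 1.5 * np.cumsum(vels, axis=0)])
        assert np.allclose(run.waypoints, expected, atol=1e-9)

    def test_full_compensation_monotone_convergence(self):
        # Single target, decoded velocities in its half-space: with
        # alpha = beta = 1 every accepted step reduces the distance.
        target_pos = np.array([0.55, 0.1, 0.1])
        targets = sc.TargetSet.from_positions([target_pos])
        start = inverse(np.array([0.40, 0.0, -0.15]))
        rng = np.random.default_rng(3)
        start_pos = forward(start).position
        to_t = target_pos - start_pos
        vels = []
        for _ in range(80):
            v = rng.normal(size=3)
            if np.dot(v, to_t) < 0:
                v = -v
            vels.append(v / np.linalg.norm(v) * 0.008)
        traj = sc.DecodedTrajectory(np.asarray(vels), true_target_id=1, direction_label=1)
        run = sc.run_trial(traj, targets, sc.SharedControlParams(1.0, 1.0), start)
        dists = np.linalg.norm(run.waypoints - target_pos, axis=1)
        assert (np.diff(dists) <= 1e-12).all()
        assert run.reached

    def test_intended_target_switching(self, layout):
        targets, start = layout
        start_pos = forward(start).position
        d1 = targets[1].position - start_pos
        d2 = targets[2].position - start_pos
        vels = np.vstack(
            [np.tile(d1 / np.linalg.norm(d1) * 0.005, (5, 1)),
             np.tile(d2 / np.linalg.norm(d2) * 0.005, (5, 1))]
        )
        traj = sc.DecodedTrajectory(velocities=vels, true_target_id=2, direction_label=2)
        run = sc.run_trial(traj, targets, sc.SharedControlParams(0.5, 1.0), start)
        assert run.intended_ids[0] == 1
        assert run.intended_ids[5] == 2  # switches within one step of the stream change

    def test_determinism(self, layout, small_ensemble):
        targets, start = layout
        params = sc.SharedControlParams(0.6, 0.6)
        r1 = sc.run_trial(small_ensemble[0], targets, params, start)
        r2 = sc.run_trial(small_ensemble[0], targets, params, start)
        np.testing.assert_array_equal(r1.waypoints, r2.waypoints)
        assert r1.intended_ids == r2.intended_ids

    def test_waypoints_time_aligned_when_not_reached(self, layout):
        targets, start = layout
        rng = np.random.default_rng(8)
        vels = rng.normal(scale=0.002, size=(15, 3))
        traj = sc.DecodedTrajectory(velocities=vels, true_target_id=1, direction_label=1)
        run = sc.run_trial(traj, targets, sc.SharedControlParams(0.3, 0.7), start)
        if not run.reached:
            assert len(run.waypoints) == 16
            assert len(run.intended_ids) == 15


class TestTargetSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            sc.TargetSet.from_positions([[0.5, 0, 0], [0.4, 0.1, 0]], ids=[1, 1])

    def test_goal_configs_solve_positions(self, layout):
        targets, _ = layout
        for t in targets.targets:
            assert np.allclose(forward(t.goal_config).position, t.position, atol=1e-9)

    def test_robot_frame_offset(self):
        ts = sc.TargetSet.from_robot_positions([[0.3, 0.1, 0.0]])
        assert np.allclose(ts.positions[0], [0.5, 0.1, 0.2])
        assert np.allclose(ts.robot_positions[0], [0.3, 0.1, 0.0])

    def test_unreachable_target_rejected(self):
        from sharedreach.kinematics import WorkspaceError

        with pytest.raises(WorkspaceError):
            sc.TargetSet.from_positions([[1.2, 0.0, 0.0]])
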