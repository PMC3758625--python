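"""Analytic arm IK: reachability clamping, solve/validate/repair behavior."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from kinfilter import check_pose_validity, clamp_to_reachable
from kinfilter import ik_solver
from kinfilter.skeleton_model import DOF_NAMES, Pose
from conftest import random_reachable_target


class TestClampToReachable:
    def test_outer_boundary_projection(self):
        out = clamp_to_reachable(np.zeros(3), np.array([900.0, 0, 0]), 300.0, 300.0)
        assert np.allclose(out, [600.0, 0, 0])

    def test_inside_annulus_unchanged(self):
        target = np.array([100.0, 0, 0])
        assert np.allclose(clamp_to_reachable(np.zeros(3), target, 300.0, 300.0), target)

    def test_inner_boundary_pushout(self):
        out = clamp_to_reachable(np.zeros(3), np.array([0.0, 0, 10.0]), 350.0, 250.0)
        assert np.allclose(out, [0, 0, 100.0 + ik_solver.INNER_REACH_EPS])

    def test_coincident_target_uses_fallback_direction(self):
        out = clamp_to_reachable(np.zeros(3), np.zeros(3), 350.0, 250.0, fallback_dir=np.array([0, 0, 1.0]))
        assert np.allclose(out / np.linalg.norm(out), [0, 0, 1.0])

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            clamp_to_reachable(np.zeros(3), np.ones(3), -1.0, 250.0)


class TestSolveArmIK:
    def test_full_extension_collinear_elbow(self, model, full_obstacles):
        S = model.shoulder_position("r")
        l_ua, l_fa = model.arm_lengths("r")
        target = S + np.array([0.0, -(l_ua + l_fa), 0.0])
        sol = ik_solver.solve_arm_ik(model, "r", S, target, obstacles=full_obstacles)
        assert sol.valid
        assert sol.angles["r_elbow_flex"] == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.norm(sol.elbow - (S + [0, -l_ua, 0])) < 1e-6

    def test_fk_roundtrip_on_random_targets(self, model, rng, full_obstacles):
        # valid (non-repaired) solutions must place the hand at the target
        n_checked = 0
        for _ in range(300):
            target = random_reachable_target(rng, model)
            sol = ik_solver.solve_arm_ik(
                model, "r", model.shoulder_position("r"), target, obstacles=full_obstacles
            )
            if not sol.valid:
                continue
            angles = {d: 0.0 for d in DOF_NAMES}
            angles.update(sol.angles)
            pose = Pose.from_angles(model, angles)
            assert np.linalg.norm(pose.joint_positions["r_hand"] - target) < 0.1
            n_checked += 1
        assert n_checked > 100  # a healthy share of random targets is directly solvable

    def test_elbow_hint_steers_swivel(self, model, rng, full_obstacles):
        S = model.shoulder_position("r")
        target = S + np.array([50.0, -150.0, 350.0])
        base = ik_solver.solve_arm_ik(model, "r", S, target, obstacles=full_obstacles)
        hint = base.elbow + np.array([0.0, 120.0, 0.0])
        steered = ik_solver.solve_arm_ik(model, "r", S, target, elbow_hint=hint, obstacles=full_obstacles)
        assert steered.valid
        assert np.linalg.norm(steered.elbow - hint) <= np.linalg.norm(base.elbow - hint) + 1e-6
        # elbow still on the reachable circle: segment lengths conserved
        l_ua, l_fa = model.arm_lengths("r")
        assert np.linalg.norm(steered.elbow - S) == pytest.approx(l_ua, abs=1e-6)
        assert np.linalg.norm(steered.hand - steered.elbow) == pytest.approx(l_fa, abs=1e-6)

    def test_agrees_with_numerical_optimizer(self, model, rng, full_obstacles):
        """Analytic angles match an independent numerical IK within 0.5 deg/DOF."""
        S = model.shoulder_position("r")
        l_ua, l_fa = model.arm_lengths("r")
        names = ["r_shoulder_flex", "r_shoulder_abd", "r_shoulder_rot", "r_elbow_flex"]
        checked = 0
        while checked < 40:
            target = random_reachable_target(rng, model, margin=30.0)
            sol = ik_solver.solve_arm_ik(model, "r", S, target, obstacles=full_obstacles)
            if not sol.valid or sol.angles["r_elbow_flex"] < 5.0:
                continue

            def residual(x):
                ang = dict(zip(names, x))
                e, h = ik_solver._arm_fk("r", S, ang, l_ua, l_fa)
                return np.concatenate([h - target, e - sol.elbow])

            x0 = np.array([sol.angles[n] for n in names]) + rng.uniform(-8, 8, 4)
            fit = least_squares(residual, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            assert fit.cost < 1e-6
            for n, v in zip(names, fit.x):
                assert abs(v - sol.angles[n]) < 0.5, n
            checked += 1


class TestCheckPoseValidity:
    def test_neutral_pose_is_valid(self, model, neutral):
        report = check_pose_validity(model, neutral)
        assert report.ok

    def test_limit_violation_names_dof(self, model):
        angles = {d: 0.0 for d in DOF_NAMES}
        angles["r_elbow_flex"] = -20.0
        report = check_pose_validity(model, Pose.from_angles(model, angles))
        assert [v[0] for v in report.limit_violations] == ["r_elbow_flex"]

    def test_crossed_forearms_collide(self, model):
        # both hands driven to the same mid-chest point without collision
        # screening: the forearm proxies must overlap
        target = np.array([0.0, 150.0, 260.0])
        angles = {d: 0.0 for d in DOF_NAMES}
        for side in ("l", "r"):
            sol = ik_solver.solve_arm_ik(
                model, side, model.shoulder_position(side), target, obstacles=[]
            )
            angles.update(sol.angles)
        report = check_pose_validity(model, Pose.from_angles(model, angles))
        assert any({"l_forearm", "r_forearm"} == set(pair) for pair in report.collision_pairs)


class TestResolveInvalidPose:
    def test_valid_target_passes_through_unchanged(self, model, rng, full_obstacles):
        # solve_arm is a no-op wrapper for targets the analytic solver accepts
        for _ in range(50):
            target = random_reachable_target(rng, model)
            direct = ik_solver.solve_arm_ik(
                model, "r", model.shoulder_position("r"), target, obstacles=full_obstacles
            )
            if not direct.valid:
                continue
            wrapped = ik_solver.solve_arm(
                model, "r", model.shoulder_position("r"), target, obstacles=full_obstacles
            )
            assert not wrapped.resolved
            assert wrapped.angles == direct.angles

    def test_hand_behind_head_rests_on_proxy_surface(self, model, full_obstacles):
        """A target hijacked into the head proxy resolves to the head surface,
        staying on the side the hand approached from (behind)."""
        head = model.head_position()
        S = model.shoulder_position("r")
        # previous pose: hand validly behind the head
        prev_sol = ik_solver.solve_arm(
            model, "r", S, head + np.array([0.0, 0.0, -170.0]), obstacles=full_obstacles
        )
        angles = {d: 0.0 for d in DOF_NAMES}
        angles.update(prev_sol.angles)
        prev_pose = Pose.from_angles(model, angles)
        sol = ik_solver.resolve_invalid_pose(
            model, "r", S, head, previous_pose=prev_pose, obstacles=full_obstacles
        )
        angles.update(sol.angles)
        report = check_pose_validity(model, Pose.from_angles(model, angles))
        assert report.ok
        head_r = model.collision_config["head_radius_frac_h"] * model.stature
        dist = np.linalg.norm(sol.hand - head)
        assert head_r < dist < head_r + 80.0  # resting near the proxy surface
        assert sol.hand[2] < head[2]  # still behind the head

    def test_hyperextension_target_clamped_to_limits(self, model, full_obstacles):
        # target requiring elbow hyperextension: inner-annulus point behind limits
        S = model.shoulder_position("r")
        target = S + np.array([0.0, -120.0, 0.0])  # well inside the flexion-limited reach
        sol = ik_solver.solve_arm(model, "r", S, target, obstacles=full_obstacles)
        angles = {d: 0.0 for d in DOF_NAMES}
        angles.update(sol.angles)
        assert check_pose_validity(model, Pose.from_angles(model, angles)).ok
        # grid-search oracle: no valid pose can get closer than the returned one
        achieved = np.linalg.norm(sol.hand - target)
        l_ua, l_fa = model.arm_lengths("r")
        rng = np.random.default_rng(0)
        for _ in range(300):
            cand = {
                d: rng.uniform(*model.joint_limits[d])
                for d in ("r_shoulder_flex", "r_shoulder_abd", "r_shoulder_rot", "r_elbow_flex")
            }
            e, h = ik_solver._arm_fk("r", S, cand, l_ua, l_fa)
            if ik_solver._arm_collides(model, "r", S, e, h, full_obstacles):
                continue
            assert np.linalg.norm(h - target) >= achieved - 25.0  # coarse optimality

    def test_monotone_degradation_beyond_reach(self, model, full_obstacles):
        # targets farther out along a fixed ray all land at the same full-extension hand
        S = model.shoulder_position("r")
        ray = np.array([0.2, -0.3, 0.93])
        ray /= np.linalg.norm(ray)
        hands = []
        for d in (700.0, 900.0, 1500.0):
            sol = ik_solver.solve_arm(model, "r", S, S + d * ray, obstacles=full_obstacles)
            hands.append(sol.hand)
        l_ua, l_fa = model.arm_lengths("r")
        assert np.linalg.norm(hands[0] - S) == pytest.approx(l_ua + l_fa, abs=1e-6)
        assert np.allclose(hands[0], hands[1], atol=1e-6)
        assert np.allclose(hands[0], hands[2], atol=1e-6)

    def test_emitted_poses_always_valid_on_fuzzed_targets(self, model, rng, full_obstacles):
        for _ in range(150):
            target = rng.uniform(-800, 800, 3)
            sol = ik_solver.solve_arm(model, "r", model.shoulder_position("r"), target, obstacles=full_obstacles)
            angles = {d: 0.0 for d in DOF_NAMES}
            angles.update(sol.angles)
            assert check_pose_validity(model, Pose.from_angles(model, angles)).ok
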