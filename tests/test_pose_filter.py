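"""Confidence gating, model-constrained pose estimation, validated interpolation."""

import numpy as np
import pytest

from kinfilter import (
    FilterConfig,
    TrackerFrame,
    check_pose_validity,
    estimate_pose,
    filter_stream,
    gate_centroids,
    interpolate_poses,
)
from kinfilter import calibration_align as ca
from kinfilter import synthetic_tracker as st
from kinfilter.pose_filter import StreamError
from kinfilter.skeleton_model import DOF_NAMES, JOINTS, Pose


def frame_from_pose(pose, t=None, confidences=None):
    conf = {j: 1.0 for j in JOINTS}
    if confidences:
        conf.update(confidences)
    return TrackerFrame(
        pose.timestamp if t is None else t,
        {j: pose.joint_positions[j].copy() for j in JOINTS},
        conf,
    )


@pytest.fixture(scope="module")
def clean_stream(model):
    truth = st.generate_motion(model, 8.0, 30.0, seed=11)
    frames = st.corrupt_stream(truth, st.CorruptionSpec(sigma={j: 0.0 for j in JOINTS}, seed=0))
    return truth, frames


class TestGateCentroids:
    def test_unreliable_hand_from_previous_observation(self, model, neutral):
        prev = frame_from_pose(neutral, t=0.0)
        prev.positions["r_hand"] = np.array([1.0, 2.0, 3.0])
        cur = frame_from_pose(neutral, t=0.1, confidences={"r_hand": 0.0})
        gated, counts = gate_centroids(cur, prev, neutral)
        assert np.allclose(gated.positions["r_hand"], [1.0, 2.0, 3.0])
        assert counts["gated_ee"] == 1

    def test_unreliable_elbow_from_previous_model(self, model, neutral):
        prev = frame_from_pose(neutral, t=0.0)
        prev.positions["r_elbow"] = np.array([9.0, 9.0, 9.0])  # raw differs from model
        cur = frame_from_pose(neutral, t=0.1, confidences={"r_elbow": 0.0})
        gated, counts = gate_centroids(cur, prev, neutral)
        assert np.allclose(gated.positions["r_elbow"], neutral.joint_positions["r_elbow"])
        assert counts["gated_ij"] == 1

    def test_fully_confident_frame_unchanged(self, model, neutral):
        prev = frame_from_pose(neutral, t=0.0)
        cur = frame_from_pose(neutral, t=0.1)
        cur.positions["r_hand"] += 5.0
        gated, counts = gate_centroids(cur, prev, neutral)
        assert sum(counts.values()) == 0
        for j in JOINTS:
            assert np.allclose(gated.positions[j], cur.positions[j])

    def test_gating_touches_only_low_confidence_joints(self, model, neutral, rng):
        prev = frame_from_pose(neutral, t=0.0)
        cur = frame_from_pose(neutral, t=0.1)
        for j in JOINTS:
            cur.positions[j] = cur.positions[j] + rng.normal(0, 20, 3)
        cur.confidence["l_hand"] = 0.0
        cur.confidence["r_elbow"] = 0.0
        cur.confidence["r_hand"] = 0.5  # tracker-estimated: kept, not replaced
        gated, _ = gate_centroids(cur, prev, neutral)
        for j in JOINTS:
            if j in ("l_hand", "r_elbow"):
                assert not np.allclose(gated.positions[j], cur.positions[j])
            else:
                assert np.allclose(gated.positions[j], cur.positions[j])

    def test_first_frame_passes_through(self, model, neutral):
        cur = frame_from_pose(neutral, t=0.0, confidences={"r_hand": 0.0})
        gated, counts = gate_centroids(cur, None, None)
        assert sum(counts.values()) == 0

    def test_confidence_domain_enforced(self, neutral):
        with pytest.raises(ValueError, match="confidence"):
            frame_from_pose(neutral, confidences={"r_hand": 0.7})


class TestEstimatePose:
    def test_noiseless_roundtrip_recovers_truth(self, model, rng):
        truth = st.generate_motion(model, 2.0, 30.0, seed=4)
        prev = None
        for pose in truth:
            est = estimate_pose(frame_from_pose(pose), model, previous_pose=prev)
            for j in ("l_hand", "r_hand", "l_elbow", "r_elbow"):
                assert np.linalg.norm(est.joint_positions[j] - pose.joint_positions[j]) < 1.0
            prev = est

    def test_unreachable_target_fully_extends_arm(self, model, neutral):
        # object in hand: centroid beyond reach, the model stretches toward it
        frame = frame_from_pose(neutral, t=0.1)
        S = model.shoulder_position("r")
        direction = np.array([-0.4, -0.2, 0.89])
        direction /= np.linalg.norm(direction)
        frame.positions["r_hand"] = S + 900.0 * direction
        est = estimate_pose(frame, model, previous_pose=neutral)
        l_ua, l_fa = model.arm_lengths("r")
        reach = np.linalg.norm(est.joint_positions["r_hand"] - S)
        assert reach == pytest.approx(l_ua + l_fa, abs=1e-3)
        cos = (est.joint_positions["r_hand"] - S) @ direction / reach
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_displaced_elbow_projected_onto_reachable_circle(self, model, neutral):
        frame = frame_from_pose(neutral, t=0.1)
        S = model.shoulder_position("r")
        frame.positions["r_hand"] = S + np.array([0.0, -150.0, 380.0])
        est0 = estimate_pose(frame, model, previous_pose=neutral)
        frame.positions["r_elbow"] = est0.joint_positions["r_elbow"] + np.array([40.0, 40.0, -50.0])
        est = estimate_pose(frame, model, previous_pose=neutral)
        l_ua, l_fa = model.arm_lengths("r")
        assert np.linalg.norm(est.joint_positions["r_elbow"] - S) == pytest.approx(l_ua, abs=1e-6)
        assert np.linalg.norm(
            est.joint_positions["r_hand"] - est.joint_positions["r_elbow"]
        ) == pytest.approx(l_fa, abs=1e-6)
        assert check_pose_validity(model, est).ok


class TestInterpolatePoses:
    def test_zero_substeps_empty(self, model, neutral):
        assert interpolate_poses(model, neutral, neutral.copy_at(0.1), 0) == []

    def test_identical_poses_constant(self, model, neutral):
        subs = interpolate_poses(model, neutral, neutral.copy_at(0.2), 3)
        assert len(subs) == 3
        for p in subs:
            for j in JOINTS:
                assert np.allclose(p.joint_positions[j], neutral.joint_positions[j], atol=1e-6)

    def test_crossing_arms_blend_stays_valid(self, model):
        # two poses whose straight-line hand blend would cross the arms
        a = {d: 0.0 for d in DOF_NAMES}
        a.update({"l_shoulder_flex": 90.0, "l_shoulder_abd": -40.0, "r_shoulder_flex": 20.0})
        b = {d: 0.0 for d in DOF_NAMES}
        b.update({"r_shoulder_flex": 90.0, "r_shoulder_abd": 40.0, "l_shoulder_flex": 20.0})
        pa = Pose.from_angles(model, a, timestamp=0.0)
        pb = Pose.from_angles(model, b, timestamp=0.2)
        assert check_pose_validity(model, pa).ok and check_pose_validity(model, pb).ok
        subs = interpolate_poses(model, pa, pb, 6)
        assert len(subs) == 6
        for p in subs:
            assert check_pose_validity(model, p).ok


class TestFilterStream:
    def test_empty_stream(self, model):
        result = filter_stream([], model)
        assert result.poses == [] and result.key_poses == []

    def test_nonmonotonic_timestamps_rejected(self, model, neutral):
        frames = [frame_from_pose(neutral, t=0.1), frame_from_pose(neutral, t=0.05)]
        with pytest.raises(StreamError):
            filter_stream(frames, model)

    def test_one_output_pose_per_frame(self, model, clean_stream):
        truth, frames = clean_stream
        result = filter_stream(frames, model, config=FilterConfig(substeps=2, learn=False))
        assert len(result.poses) == len(frames)
        assert len(result.key_poses) == len(frames)
        assert len(result.substep_poses) == len(frames)

    def test_elbow_error_not_worse_than_raw(self, model):
        truth = st.generate_motion(model, 8.0, 30.0, seed=21)
        frames = st.corrupt_stream(truth, st.CorruptionSpec(seed=22))
        result = filter_stream(frames, model, config=FilterConfig(substeps=0))
        raw = np.mean(
            [
                np.linalg.norm(frames[k].positions[j] - truth[k].joint_positions[j])
                for k in range(len(truth))
                for j in ("l_elbow", "r_elbow")
            ]
        )
        filt = np.mean(
            [
                np.linalg.norm(result.key_poses[k].joint_positions[j] - truth[k].joint_positions[j])
                for k in range(len(truth))
                for j in ("l_elbow", "r_elbow")
            ]
        )
        assert filt < raw

    def test_cubic_delay_is_two_samples(self, model, clean_stream):
        truth, frames = clean_stream
        result = filter_stream(frames, model, config=FilterConfig(substeps=0, learn=False))
        ta = np.stack([p.joint_positions["r_hand"] for p in truth])
        tb = np.stack([p.joint_positions["r_hand"] for p in result.poses])
        res = ca.temporal_align({"hand": ta}, {"hand": tb}, max_lag=8)
        assert res.chosen_lag == 2
        assert result.delay_samples == 2

    @pytest.mark.parametrize("mode, delay", [("linear", 1), ("off", 0)])
    def test_alternative_interpolators_delay(self, model, clean_stream, mode, delay):
        truth, frames = clean_stream
        result = filter_stream(frames, model, config=FilterConfig(interpolator=mode, substeps=0, learn=False))
        ta = np.stack([p.joint_positions["r_hand"] for p in truth])
        tb = np.stack([p.joint_positions["r_hand"] for p in result.poses])
        assert ca.temporal_align({"hand": ta}, {"hand": tb}, max_lag=8).chosen_lag == delay
        assert result.delay_samples == delay

    def test_hand_trajectory_continuous_through_occlusion(self, model):
        truth = st.generate_motion(model, 8.0, 30.0, seed=31)
        spec = st.CorruptionSpec(
            sigma={j: 0.0 for j in JOINTS}, occlusions=[("r_hand", (100, 130), 0.0)], seed=32
        )
        frames = st.corrupt_stream(truth, spec)
        cfg = FilterConfig(substeps=0, learn=False)
        result = filter_stream(frames, model, config=cfg)
        hand = np.stack([p.joint_positions["r_hand"] for p in result.poses])
        steps = np.linalg.norm(np.diff(hand, axis=0), axis=1)
        # re-acquisition is slew-limited: no output jump exceeds the configured
        # per-frame motion bound, even though the raw stream teleports
        raw_jump = np.linalg.norm(frames[131].positions["r_hand"] - frames[130].positions["r_hand"])
        assert raw_jump > cfg.max_reacquire_step  # the occlusion did create a teleport
        assert steps.max() <= 2.0 * cfg.max_reacquire_step

    def test_all_emitted_poses_valid_on_noisy_stream(self, model):
        truth = st.generate_motion(model, 5.0, 30.0, seed=41)
        frames = st.corrupt_stream(truth, st.CorruptionSpec(seed=42))
        result = filter_stream(frames, model, config=FilterConfig(substeps=2))
        for pose in result.key_poses + [p for subs in result.substep_poses for p in subs]:
            assert check_pose_validity(model, pose).ok

    def test_learner_consumes_raw_centroids(self, model):
        # an occluded (c=0) hand freezes learning for that forearm even though
        # the filter keeps producing hand poses
        truth = st.generate_motion(model, 3.0, 30.0, seed=51)
        spec = st.CorruptionSpec(
            sigma={j: 0.0 for j in JOINTS}, occlusions=[("r_hand", (0, 89), 0.0)], seed=5
        )
        frames = st.corrupt_stream(truth, spec)
        result = filter_stream(frames, model, config=FilterConfig(substeps=0, learn=True))
        assert result.learner["r_forearm"].k == 0
        assert result.learner["l_forearm"].k == len(frames)
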