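"""Per-frame pose reinforcement: confidence gating, model-constrained IK, interpolation.

The filter turns a raw tracker stream into a sequence of poses that are valid
by construction (joint limits, limb lengths, no self-collision):

1. *Gating*: centroids with confidence below 0.5 are replaced — end effectors
   (hands) by their previous raw observation, intermediate joints (elbows) by
   the model's previous position.
2. *Pose estimation*: each hand target is clamped into the arm's reach
   annulus and solved by analytic IK; the elbow is read back from the posed
   model (the gated elbow centroid only steers the redundant swivel, so the
   output elbow always lies on the kinematically reachable circle).
3. *Interpolation*: consecutive key poses are joined by a cubic Hermite
   spline on the hand trajectories, each substep re-solved through IK and
   validated.  The cubic interpolator needs the trajectory slope at a key
   point, hence one future key frame, so the emitted stream lags the input by
   a constant two samples (~66 ms at 30 fps); a linear interpolator (one
   sample) or no interpolation (zero lag) can be selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ik_solver, limb_learning
from .skeleton_model import (
    END_EFFECTORS,
    INTERMEDIATE_JOINTS,
    JOINTS,
    KinematicModel,
    Pose,
)


class StreamError(ValueError):
    """The frame stream violates its contract (e.g. non-monotone timestamps)."""


@dataclass
class TrackerFrame:
    """One raw tracker sample: timestamp, per-joint centroid and confidence."""

    t: float
    positions: dict[str, np.ndarray]  # mm, torso-referenced
    confidence: dict[str, float]  # in {0, 0.5, 1}

    def __post_init__(self):
        missing = [j for j in JOINTS if j not in self.positions or j not in self.confidence]
        if missing:
            raise ValueError(f"frame at t={self.t} missing joints: {missing}")
        bad = {j: c for j, c in self.confidence.items() if c not in (0.0, 0.5, 1.0)}
        if bad:
            raise ValueError(f"confidence values must be in {{0, 0.5, 1}}, got {bad}")

    def copy(self) -> "TrackerFrame":
        return TrackerFrame(
            self.t,
            {j: np.asarray(p, float).copy() for j, p in self.positions.items()},
            dict(self.confidence),
        )


@dataclass
class FilterConfig:
    """Tunables of the stream filter."""

    interpolator: str = "cubic"  # cubic | linear | off
    substeps: int = 4
    learn: bool = True
    learner: limb_learning.LearnerConfig = field(default_factory=limb_learning.LearnerConfig)
    gate_ee_from_model: bool = False  # use the model (not the raw observation) for gated hands
    gate_others_from_model: bool = False  # also hold low-confidence shoulders/head/torso from the model
    swivel_samples: int = 64
    # after an occlusion ends, the hand target approaches the re-acquired
    # centroid at most this fast, so the output never teleports (mm per frame)
    max_reacquire_step: float = 100.0

    def __post_init__(self):
        if self.interpolator not in ("cubic", "linear", "off"):
            raise ValueError(f"unknown interpolator {self.interpolator!r}")
        if self.substeps < 0:
            raise ValueError("substeps must be >= 0")


@dataclass
class FilterResult:
    """Output of :func:`filter_stream`."""

    poses: list[Pose]  # emitted stream, one per input frame (delayed per interpolator)
    key_poses: list[Pose]  # solved pose per input frame, index-aligned with the input
    substep_poses: list[list[Pose]]  # validated interpolated poses emitted with each frame
    learner: dict[str, limb_learning.LimbLengthState]
    model: KinematicModel  # with adapted limb lengths
    log: dict

    @property
    def delay_samples(self) -> int:
        return self.log["delay_samples"]


def gate_centroids(
    frame: TrackerFrame,
    previous_frame: TrackerFrame | None,
    previous_pose: Pose | None,
    config: FilterConfig | None = None,
) -> tuple[TrackerFrame, dict]:
    """Replace unreliable centroids (confidence < 0.5).

    Hands fall back to the previous raw observation (or the model when
    ``gate_ee_from_model``), elbows to the model's previous position.  All
    other joints pass through unchanged unless ``gate_others_from_model``.
    On the first frame there is no history, so the frame passes through.
    """
    config = config or FilterConfig()
    counts = {"gated_ee": 0, "gated_ij": 0, "gated_other": 0}
    if previous_frame is None or previous_pose is None:
        return frame.copy(), counts
    gated = frame.copy()
    for joint in JOINTS:
        if frame.confidence[joint] >= 0.5:
            continue
        if joint in END_EFFECTORS:
            source = previous_pose.joint_positions if config.gate_ee_from_model else previous_frame.positions
            gated.positions[joint] = np.asarray(source[joint], float).copy()
            counts["gated_ee"] += 1
        elif joint in INTERMEDIATE_JOINTS:
            gated.positions[joint] = previous_pose.joint_positions[joint].copy()
            counts["gated_ij"] += 1
        elif config.gate_others_from_model:
            gated.positions[joint] = previous_pose.joint_positions[joint].copy()
            counts["gated_other"] += 1
    return gated, counts


def estimate_pose(
    gated: TrackerFrame,
    model: KinematicModel,
    previous_pose: Pose | None = None,
    config: FilterConfig | None = None,
    log: dict | None = None,
) -> Pose:
    """Best valid model pose for one gated frame.

    Arms are solved left then right; each solve sees the torso/head proxies
    plus the other arm's current geometry, so the emitted pose carries no
    self-collision.  The returned pose is FK-consistent with the model.
    """
    statics = ik_solver.static_obstacles(model)
    angles: dict[str, float] = {}
    solutions = {}
    for side in ("l", "r"):
        obstacles = list(statics)
        other = "r" if side == "l" else "l"
        if other in solutions:
            s = solutions[other]
            obstacles += ik_solver._arm_geoms(model, other, model.shoulder_position(other), s.elbow, s.hand)
        elif previous_pose is not None:
            obstacles += ik_solver._arm_geoms(
                model,
                other,
                model.shoulder_position(other),
                previous_pose.joint_positions[f"{other}_elbow"],
                previous_pose.joint_positions[f"{other}_hand"],
            )
        sol = ik_solver.solve_arm(
            model,
            side,
            model.shoulder_position(side),
            gated.positions[f"{side}_hand"],
            previous_pose=previous_pose,
            elbow_hint=gated.positions[f"{side}_elbow"],
            obstacles=obstacles,
        )
        solutions[side] = sol
        angles.update(sol.angles)
        if log is not None and sol.resolved:
            log["resolved"] = log.get("resolved", 0) + 1
    pose = Pose.from_angles(model, angles, timestamp=gated.t)
    report = ik_solver.check_pose_validity(model, pose)
    if not report.ok:
        # rare: the left arm was solved against the *previous* right arm; re-resolve it
        s = solutions["r"]
        obstacles = list(statics) + ik_solver._arm_geoms(model, "r", model.shoulder_position("r"), s.elbow, s.hand)
        sol_l = ik_solver.resolve_invalid_pose(
            model, "l", model.shoulder_position("l"), gated.positions["l_hand"],
            previous_pose=previous_pose, obstacles=obstacles,
        )
        angles.update(sol_l.angles)
        pose = Pose.from_angles(model, angles, timestamp=gated.t)
        if log is not None:
            log["re_resolved"] = log.get("re_resolved", 0) + 1
        if not ik_solver.check_pose_validity(model, pose).ok:
            neutral = {d: 0.0 for d in model.joint_limits}
            pose = Pose.from_angles(model, neutral, timestamp=gated.t)
            if log is not None:
                log["fallback_neutral"] = log.get("fallback_neutral", 0) + 1
    return pose


def _hermite(p0, p1, m0, m1, dt, tau):
    """Cubic Hermite basis on [0, 1]; slopes m are per unit time (mm/s)."""
    h00 = 2 * tau**3 - 3 * tau**2 + 1
    h10 = tau**3 - 2 * tau**2 + tau
    h01 = -2 * tau**3 + 3 * tau**2
    h11 = tau**3 - tau**2
    return h00 * p0 + h10 * dt * m0 + h01 * p1 + h11 * dt * m1


def interpolate_poses(
    model: KinematicModel,
    previous_pose: Pose,
    new_pose: Pose,
    substeps: int,
    slopes: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    config: FilterConfig | None = None,
    log: dict | None = None,
) -> list[Pose]:
    """Validated poses at ``substeps`` interior times between two key poses.

    Hand trajectories follow a cubic Hermite segment (``slopes`` maps each
    hand to its (start, end) velocity in mm/s; without slopes the blend is
    linear — the two-key warm-up fallback).  Every substep is re-solved
    through IK with the linearly blended elbow as swivel hint and audited, so
    arm-crossing blends cannot emit colliding intermediate poses.
    """
    if substeps < 0:
        raise ValueError("substeps must be >= 0")
    if substeps == 0:
        return []
    t0, t1 = previous_pose.timestamp, new_pose.timestamp
    dt = t1 - t0
    out: list[Pose] = []
    last = previous_pose
    for j in range(1, substeps + 1):
        tau = j / (substeps + 1)
        t = t0 + tau * dt
        targets = {}
        hints = {}
        for hand in END_EFFECTORS:
            p0 = previous_pose.joint_positions[hand]
            p1 = new_pose.joint_positions[hand]
            if slopes is not None and hand in slopes and dt > 0:
                m0, m1 = slopes[hand]
                targets[hand] = _hermite(p0, p1, m0, m1, dt, tau)
            else:
                targets[hand] = (1 - tau) * p0 + tau * p1
            elbow = hand.replace("hand", "elbow")
            hints[hand] = (1 - tau) * previous_pose.joint_positions[elbow] + tau * new_pose.joint_positions[elbow]
        frame = TrackerFrame(
            t,
            {
                **{j_: last.joint_positions[j_].copy() for j_ in JOINTS},
                "l_hand": targets["l_hand"],
                "r_hand": targets["r_hand"],
                "l_elbow": hints["l_hand"],
                "r_elbow": hints["r_hand"],
            },
            {j_: 1.0 for j_ in JOINTS},
        )
        pose = estimate_pose(frame, model, previous_pose=last, config=config, log=log)
        out.append(pose)
        last = pose
    return out


def _key_slope(keys: list[Pose], i: int, hand: str) -> np.ndarray:
    """Finite-difference trajectory slope at key point i (central where possible)."""
    lo = max(0, i - 1)
    hi = min(len(keys) - 1, i + 1)
    dt = keys[hi].timestamp - keys[lo].timestamp
    if dt <= 0:
        return np.zeros(3)
    return (keys[hi].joint_positions[hand] - keys[lo].joint_positions[hand]) / dt


def filter_stream(
    frames,
    model: KinematicModel,
    learner_states: dict[str, limb_learning.LimbLengthState] | None = None,
    config: FilterConfig | None = None,
) -> FilterResult:
    """Run the full reinforcement filter over a time-ordered frame sequence.

    Limb learning consumes the raw centroids of each frame before gating;
    pose estimation consumes the current length estimates — the deterministic
    interleave of the two parallel processes.  One pose is emitted per input
    frame, delayed by 2 samples (cubic), 1 (linear) or 0 (off), plus the
    validated interpolation substeps for the segment being played out.
    """
    config = config or FilterConfig()
    model = model.copy()
    states = learner_states if learner_states is not None else limb_learning.new_learner_states()
    delay = {"cubic": 2, "linear": 1, "off": 0}[config.interpolator]
    log: dict = {
        "frames": 0,
        "delay_samples": delay,
        "gated_ee": 0,
        "gated_ij": 0,
        "gated_other": 0,
        "clamped_targets": 0,
        "resolved": 0,
        "learner_resets": 0,
    }
    keys: list[Pose] = []
    out_poses: list[Pose] = []
    out_substeps: list[list[Pose]] = []
    prev_frame: TrackerFrame | None = None
    prev_pose: Pose | None = None
    prev_t = None
    catchup: set[str] = set()
    for frame in frames:
        if prev_t is not None and frame.t <= prev_t:
            raise StreamError(f"non-monotonic timestamps: {frame.t} after {prev_t}")
        prev_t = frame.t
        log["frames"] += 1
        if config.learn:
            states = limb_learning.learner_step(states, frame, config.learner, model=model)
        gated, counts = gate_centroids(frame, prev_frame, prev_pose, config)
        for k, v in counts.items():
            log[k] += v
        # slew-limited catch-up after an occlusion: the hand target walks from
        # the held position toward the re-acquired centroid step by step
        for hand in END_EFFECTORS:
            reacquired = (
                prev_frame is not None
                and prev_frame.confidence[hand] < 0.5
                and frame.confidence[hand] >= 0.5
            )
            if reacquired:
                catchup.add(hand)
            if hand in catchup and prev_pose is not None:
                anchor = prev_pose.joint_positions[hand]
                delta = gated.positions[hand] - anchor
                dist = float(np.linalg.norm(delta))
                if dist > config.max_reacquire_step:
                    gated.positions[hand] = anchor + (config.max_reacquire_step / dist) * delta
                    log["reacquire_limited"] = log.get("reacquire_limited", 0) + 1
                else:
                    catchup.discard(hand)
        for side in ("l", "r"):
            l_ua, l_fa = model.arm_lengths(side)
            d = float(np.linalg.norm(gated.positions[f"{side}_hand"] - model.shoulder_position(side)))
            if d > l_ua + l_fa or d < abs(l_ua - l_fa) + ik_solver.INNER_REACH_EPS:
                log["clamped_targets"] += 1
        pose = estimate_pose(gated, model, previous_pose=prev_pose, config=config, log=log)
        keys.append(pose)
        k = len(keys) - 1

        if config.interpolator == "off":
            out_poses.append(keys[k])
            out_substeps.append([])
        elif config.interpolator == "linear":
            i = max(0, k - 1)
            out_poses.append(keys[i].copy_at(frame.t))
            if k >= 1 and config.substeps > 0:
                subs = interpolate_poses(model, keys[k - 1], keys[k], config.substeps, slopes=None, config=config, log=log)
            else:
                subs = []
            out_substeps.append(subs)
        else:  # cubic, two-sample delay
            i = max(0, k - 2)
            out_poses.append(keys[i].copy_at(frame.t))
            if k >= 2 and config.substeps > 0:
                a, b = k - 2, k - 1
                slopes = {
                    hand: (_key_slope(keys, a, hand), _key_slope(keys, b, hand)) for hand in END_EFFECTORS
                }
                subs = interpolate_poses(model, keys[a], keys[b], config.substeps, slopes=slopes, config=config, log=log)
            else:
                subs = []
            out_substeps.append(subs)
        prev_frame = frame
        prev_pose = pose
    log["learner_resets"] = sum(s.resets for s in states.values())
    return FilterResult(
        poses=out_poses,
        key_poses=keys,
        substep_poses=out_substeps,
        learner=states,
        model=model,
        log=log,
    )
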