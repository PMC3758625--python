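"""Synthetic depth-tracker emulator: ground-truth motion, corruption, region scoring.

No public recordings of an OpenNI-style centroid stream exist, so this module
generates one: smooth ground-truth upper-body motion (splines through random
way-poses inside the joint limits, repaired to be self-collision free) and a
corruption stage reproducing the documented failure modes of depth trackers:

* per-joint Gaussian centroid noise, with elbow noise growing with arm
  extension (the elbow centroid oscillates most on a stretched arm),
* occlusions: confidence drops to 0 (lost) or 0.5 (tracker-estimated), the
  reported position freezing at the last reliable value plus drift,
* depth hijack: an occluded hand keeps confidence 1 but inherits the camera
  depth of the occluding body part (head or torso),
* object-in-hand: the hand centroid slides along the forearm axis, inflating
  the apparent forearm.

Sequences are scored the way occlusion experiments are labeled: each frame a
joint is *behind*, *aligned with* or *in front of* a reference joint by
thresholding the camera-distance difference at ``theta_d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from scipy.interpolate import CubicSpline

from . import ik_solver
from .pose_filter import TrackerFrame
from .skeleton_model import DOF_NAMES, JOINTS, KinematicModel, Pose

#: camera origin in the torso frame (mm): ~1.7 m in front of the performer
DEFAULT_CAMERA = np.array([0.0, 0.0, 1700.0])

#: per-joint centroid noise (mm, per axis) matching depth-tracker error scales:
#: hands are noisiest (hand pose changes the centroid), elbows oscillate,
#: torso/head/shoulders are stable
DEFAULT_SIGMA = {
    "torso": 5.0,
    "head": 5.0,
    "l_shoulder": 8.0,
    "r_shoulder": 8.0,
    "l_elbow": 30.0,
    "r_elbow": 30.0,
    "l_hand": 20.0,
    "r_hand": 20.0,
}

CATEGORIES = ("behind", "aligned", "in_front")


@dataclass
class CorruptionSpec:
    """How to degrade a truth sequence into a tracker stream."""

    sigma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    occlusions: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)
    depth_hijacks: list[tuple[str, tuple[int, int], str]] = field(default_factory=list)
    objects_in_hand: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)
    elbow_extension_gain: float = 2.0  # sigma multiplier slope vs extension ratio
    occlusion_drift_sigma: float = 5.0  # mm/frame random walk for c=0.5 estimates
    camera: np.ndarray = field(default_factory=lambda: DEFAULT_CAMERA.copy())
    seed: int = 0

    def __post_init__(self):
        for j, s in self.sigma.items():
            if s < 0:
                raise ValueError(f"negative noise sigma for {j}")
        for _, (a, b), level in self.occlusions:
            if level not in (0.0, 0.5):
                raise ValueError("occlusion confidence level must be 0 or 0.5")
            if a > b:
                raise ValueError("occlusion interval reversed")


def _sample_waypoint(rng: np.random.Generator, model: KinematicModel, margin: float = 0.2) -> dict[str, float]:
    angles = {}
    for dof, (lo, hi) in model.joint_limits.items():
        span = hi - lo
        angles[dof] = float(rng.uniform(lo + margin * span, hi - margin * span))
    return angles


def generate_motion(
    model: KinematicModel,
    duration: float,
    rate: float,
    motion_spec="random",
    seed: int = 0,
    waypoint_interval: float = 2.0,
) -> list[Pose]:
    """Smooth, valid ground-truth pose sequence.

    ``motion_spec`` is either ``"random"`` (way-poses drawn inside the joint
    limits, rejection-sampled so every way-pose is valid) or an explicit list
    of ``(time, angles)`` waypoints.  Angle trajectories are cubic splines
    through the waypoints; any sampled frame that lands invalid (spline
    overshoot between valid way-poses) is repaired by re-solving its hand
    positions through the IK machinery, which projects it back onto the valid
    manifold.  Deterministic under ``seed``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    n_frames = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    if isinstance(motion_spec, str) and motion_spec == "random":
        n_way = max(4, int(np.ceil(duration / waypoint_interval)) + 1)
        way_times = np.linspace(0.0, duration, n_way)
        waypoints = []
        for _ in way_times:
            for _attempt in range(200):
                angles = _sample_waypoint(rng, model)
                pose = Pose.from_angles(model, angles)
                if ik_solver.check_pose_validity(model, pose).ok:
                    waypoints.append(angles)
                    break
            else:
                raise RuntimeError("could not sample a valid way-pose")
    else:
        way_times = np.array([t for t, _ in motion_spec], float)
        waypoints = [dict(a) for _, a in motion_spec]
        for angles in waypoints:
            pose = Pose.from_angles(model, angles)
            if ik_solver.check_pose_validity(model, pose).limit_violations:
                raise ValueError("motion_spec waypoint violates joint limits")
        if len(waypoints) < 2:
            raise ValueError("need at least 2 waypoints")

    names = list(model.joint_limits)
    ctrl = np.array([[w[d] for d in names] for w in waypoints])
    if len(waypoints) >= 4:
        spline = CubicSpline(way_times, ctrl, axis=0, bc_type="clamped")
    else:
        spline = CubicSpline(way_times, ctrl, axis=0, bc_type="natural")
    times = np.arange(n_frames) / rate
    times = np.clip(times, way_times[0], way_times[-1])
    sampled = spline(times)
    # clamp spline overshoot back into the limit box
    for i, d in enumerate(names):
        lo, hi = model.joint_limits[d]
        sampled[:, i] = np.clip(sampled[:, i], lo, hi)

    poses: list[Pose] = []
    prev: Pose | None = None
    for k in range(n_frames):
        angles = {d: float(sampled[k, i]) for i, d in enumerate(names)}
        pose = Pose.from_angles(model, angles, timestamp=float(times[k]))
        if not ik_solver.check_pose_validity(model, pose).ok:
            # repair: re-solve each arm toward the spline's hand position
            fixed = {}
            statics = ik_solver.static_obstacles(model)
            for side in ("l", "r"):
                sol = ik_solver.solve_arm(
                    model, side, model.shoulder_position(side),
                    pose.joint_positions[f"{side}_hand"],
                    previous_pose=prev,
                    elbow_hint=pose.joint_positions[f"{side}_elbow"],
                    obstacles=statics,
                )
                fixed.update(sol.angles)
            pose = Pose.from_angles(model, fixed, timestamp=float(times[k]))
            if not ik_solver.check_pose_validity(model, pose).ok and prev is not None:
                pose = prev.copy_at(float(times[k]))
        poses.append(pose)
        prev = pose
    return poses


def corrupt_stream(truth: list[Pose], spec: CorruptionSpec) -> list[TrackerFrame]:
    """Degrade a truth pose sequence into a raw tracker stream.

    Side-effect free: the truth sequence is never modified, and the output is
    bitwise reproducible for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(truth)
    occl = {}  # (joint, frame) -> level
    for joint, (a, b), level in spec.occlusions:
        for k in range(max(0, a), min(n - 1, b) + 1):
            occl[(joint, k)] = level
    hijack = {}
    for hand, (a, b), donor in spec.depth_hijacks:
        for k in range(max(0, a), min(n - 1, b) + 1):
            hijack[(hand, k)] = donor
    obj = {}
    for hand, (a, b), offset in spec.objects_in_hand:
        for k in range(max(0, a), min(n - 1, b) + 1):
            obj[(hand, k)] = offset

    frames: list[TrackerFrame] = []
    last_reliable: dict[str, np.ndarray] = {}
    for k, pose in enumerate(truth):
        positions = {}
        confidence = {}
        for joint in JOINTS:
            p = pose.joint_positions[joint].copy()
            sigma = spec.sigma.get(joint, 0.0)
            if joint.endswith("elbow"):
                side = joint[0]
                sh = pose.joint_positions[f"{side}_shoulder"]
                el = pose.joint_positions[joint]
                ha = pose.joint_positions[f"{side}_hand"]
                reach = np.linalg.norm(el - sh) + np.linalg.norm(ha - el)
                ext = float(np.linalg.norm(ha - sh) / reach) if reach > 0 else 0.0
                sigma = sigma * (1.0 + spec.elbow_extension_gain * ext)
            if sigma > 0:
                p = p + rng.normal(0.0, sigma, size=3)
            if (joint, k) in obj:
                side = joint[0]
                axis = pose.joint_positions[joint] - pose.joint_positions[f"{side}_elbow"]
                norm = np.linalg.norm(axis)
                if norm > 1e-9:
                    p = p + obj[(joint, k)] * axis / norm
            if (joint, k) in hijack:
                donor = hijack[(joint, k)]
                p[2] = pose.joint_positions[donor][2] + rng.normal(0.0, 5.0)
                confidence[joint] = 1.0
            if (joint, k) in occl:
                level = occl[(joint, k)]
                stale = last_reliable.get(joint, pose.joint_positions[joint])
                p = stale + rng.normal(0.0, spec.occlusion_drift_sigma, size=3)
                confidence[joint] = level
            positions[joint] = p
            confidence.setdefault(joint, 1.0)
            if confidence[joint] == 1.0 and (joint, k) not in hijack:
                last_reliable[joint] = p
        frames.append(TrackerFrame(pose.timestamp, positions, confidence))
    return frames


def camera_distance(point: np.ndarray, camera: np.ndarray = DEFAULT_CAMERA) -> float:
    return float(np.linalg.norm(np.asarray(point, float) - np.asarray(camera, float)))


def label_regions(
    positions_seq,
    joints,
    reference: str,
    theta_d: float,
    camera: np.ndarray = DEFAULT_CAMERA,
    farther_is_behind: bool = True,
) -> list[dict[str, str]]:
    """Per-frame behind / aligned / in_front category of each labeled joint.

    ``d = camera_distance(joint) - camera_distance(reference)``; ``d > theta_d``
    is *behind* (farther from the camera than the reference), ``d < -theta_d``
    is *in_front*, otherwise *aligned*.  ``positions_seq`` is a sequence of
    joint→position mappings (Pose objects and TrackerFrames are accepted).
    """
    sign = 1.0 if farther_is_behind else -1.0
    out = []
    for item in positions_seq:
        positions = getattr(item, "joint_positions", None) or getattr(item, "positions", None) or item
        ref_d = camera_distance(positions[reference], camera)
        labels = {}
        for j in joints:
            d = sign * (camera_distance(positions[j], camera) - ref_d)
            labels[j] = "behind" if d > theta_d else ("in_front" if d < -theta_d else "aligned")
        out.append(labels)
    return out


def evaluate_categories(
    estimated_seq,
    truth_labels: list[dict[str, str]],
    joints,
    reference: str,
    theta_d: float,
    camera: np.ndarray = DEFAULT_CAMERA,
) -> dict:
    """Fraction of frames whose estimated joint lands in its labeled category.

    Returns per-joint and overall percentages with frame counts.
    """
    est_labels = label_regions(estimated_seq, joints, reference, theta_d, camera)
    if len(est_labels) != len(truth_labels):
        raise ValueError(f"sequence length mismatch: {len(est_labels)} vs {len(truth_labels)}")
    per_joint = {}
    total_correct = 0
    total_frames = 0
    for j in joints:
        correct = sum(1 for e, t in zip(est_labels, truth_labels) if e[j] == t[j])
        per_joint[j] = {"frames": len(est_labels), "percent_correct": 100.0 * correct / max(1, len(est_labels))}
        total_correct += correct
        total_frames += len(est_labels)
    return {
        "per_joint": per_joint,
        "overall": {"frames": total_frames, "percent_correct": 100.0 * total_correct / max(1, total_frames)},
    }


# ---------------------------------------------------------------------------
# scenario presets


def torso_occlusion_scenario(
    model: KinematicModel,
    duration: float = 20.0,
    rate: float = 30.0,
    seed: int = 0,
) -> tuple[list[Pose], CorruptionSpec, list[tuple[int, int]]]:
    """Hand-behind-the-back gesture with depth hijack during the hidden phases.

    The right hand cycles between a reach in front of the chest and a position
    behind the back near the spine.  While the hand is behind the torso the
    tracker cannot see it; the emulated failure keeps confidence 1 but
    substitutes the torso's camera depth (the documented hijack).  Returns the
    truth poses, the corruption spec, and the hijacked frame intervals.
    """
    # Hand path in cylindrical coordinates around the torso axis: azimuth 0 is
    # the camera direction (+z), growing toward the performer's right (-x).
    # The hand arcs front -> right side -> behind the back and returns, always
    # routed around the body, never through it.
    cycle = 4.0  # s per front->behind->front cycle
    az_keys = np.array([20.0, 90.0, 155.0])  # deg: front, side, behind
    rad_keys = np.array([342.0, 470.0, 183.0])  # mm from torso axis
    y_keys = np.array([150.0, 30.0, -60.0])  # mm height relative to torso root

    def target_at(phase: float) -> np.ndarray:
        # dwell at the extremes, sweep the arc in between
        if phase < 0.15 or phase >= 0.85:
            az = az_keys[0]
        elif phase < 0.40:
            az = np.interp(phase, [0.15, 0.40], [az_keys[0], az_keys[-1]])
        elif phase < 0.60:
            az = az_keys[-1]
        else:
            az = np.interp(phase, [0.60, 0.85], [az_keys[-1], az_keys[0]])
        radius = np.interp(az, az_keys, rad_keys)
        y = np.interp(az, az_keys, y_keys)
        a = math.radians(az)
        return np.array([-radius * math.sin(a), y, radius * math.cos(a)])

    way: list[tuple[float, dict[str, float]]] = []
    statics = ik_solver.static_obstacles(model)
    prev_pose: Pose | None = None
    n_way_per_cycle = 16
    t = 0.0
    while t <= duration + 1e-9:
        phase = (t % cycle) / cycle
        sol = ik_solver.solve_arm(
            model, "r", model.shoulder_position("r"), target_at(phase),
            previous_pose=prev_pose, obstacles=statics,
        )
        angles = {d: 0.0 for d in DOF_NAMES}
        angles.update(sol.angles)
        way.append((t, angles))
        prev_pose = Pose.from_angles(model, angles, timestamp=t)
        t += cycle / n_way_per_cycle
    truth = generate_motion(model, duration, rate, motion_spec=way, seed=seed)

    # hijack whenever the torso actually occludes the truth hand: the hand is
    # behind the body (z < 0) and inside its silhouette seen from the camera
    torso_r = model.collision_config["torso_radius_frac_h"] * model.stature
    intervals = []
    start = None
    for k, pose in enumerate(truth):
        hand = pose.joint_positions["r_hand"]
        hidden = hand[2] < 0.0 and abs(hand[0]) < torso_r
        if hidden and start is None:
            start = k
        elif not hidden and start is not None:
            intervals.append((start, k - 1))
            start = None
    if start is not None:
        intervals.append((start, len(truth) - 1))
    spec = CorruptionSpec(
        depth_hijacks=[("r_hand", iv, "torso") for iv in intervals],
        seed=seed,
    )
    return truth, spec, intervals
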