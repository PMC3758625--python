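"""Articulated upper-body model: topology, anthropometry, joint limits, forward kinematics.

The model covers the eight upper-body joints a depth-sensor skeleton tracker
reports (torso, head, both shoulders, elbows and hands).  All positions are in
millimeters, expressed in a right-handed torso-centered frame:

* origin: torso centroid,
* ``+y``: up,
* ``+z``: toward the camera (out of the performer's chest),
* ``+x``: the performer's left.

Segment lengths are initialized from the performer's stature ``H`` using the
classical Drillis–Contini body-segment proportions; they can later be refined
online by :mod:`kinfilter.limb_learning`.  Each arm has four rotational degrees
of freedom: three at the shoulder (flexion about x, positive forward; abduction
about z, positive toward +x; internal rotation about the upper-arm axis) and
one elbow flexion hinge (0 deg = straight, positive bends the hand forward).
In the zero-angle reference pose both arms hang straight down along -y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

JOINTS = (
    "torso",
    "head",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_hand",
    "r_hand",
)

#: segments as (name, parent_joint, child_joint); they form a tree rooted at torso
SEGMENTS = (
    ("neck", "torso", "head"),
    ("l_clavicle", "torso", "l_shoulder"),
    ("r_clavicle", "torso", "r_shoulder"),
    ("l_upper_arm", "l_shoulder", "l_elbow"),
    ("r_upper_arm", "r_shoulder", "r_elbow"),
    ("l_forearm", "l_elbow", "l_hand"),
    ("r_forearm", "r_elbow", "r_hand"),
)

END_EFFECTORS = ("l_hand", "r_hand")
INTERMEDIATE_JOINTS = ("l_elbow", "r_elbow")

#: eye height is 0.936 H in the Drillis–Contini proportions
EYE_HEIGHT_RATIO = 0.936

# Segment lengths as fractions of stature H (Drillis–Contini body-segment
# proportions; clavicle = half biacromial width, neck/torso offsets place the
# shoulder line and face centroid relative to the mid-torso root).
DEFAULT_RATIOS: dict[str, float] = {
    "l_upper_arm": 0.186,
    "r_upper_arm": 0.186,
    "l_forearm": 0.146,
    "r_forearm": 0.146,
    "l_clavicle": 0.129,
    "r_clavicle": 0.129,
    "neck": 0.355,
    "shoulder_rise": 0.235,  # vertical offset torso root -> shoulder line
}

# Range-of-motion defaults (degrees).  Values follow standard clinical
# goniometry tables: shoulder flexion 180 / extension 60, abduction 90 in this
# decomposition (overhead reach enters through flexion), elbow flexion 0-145
# with no hyperextension.  Editable configuration, not a hard-coded truth.
DEFAULT_JOINT_LIMITS: dict[str, tuple[float, float]] = {
    "l_shoulder_flex": (-60.0, 180.0),
    "l_shoulder_abd": (-45.0, 90.0),
    "l_shoulder_rot": (-90.0, 90.0),
    "l_elbow_flex": (0.0, 145.0),
    "r_shoulder_flex": (-60.0, 180.0),
    "r_shoulder_abd": (-90.0, 45.0),
    "r_shoulder_rot": (-90.0, 90.0),
    "r_elbow_flex": (0.0, 145.0),
}

DOF_NAMES = tuple(DEFAULT_JOINT_LIMITS)

# Collision proxy configuration.  Arm capsule radii are fractions of the
# segment length; torso capsule and head sphere scale with stature.
DEFAULT_COLLISION: dict[str, float] = {
    "upper_arm_radius_frac": 0.14,
    "forearm_radius_frac": 0.12,
    "torso_radius_frac_h": 0.065,
    "torso_axis_lo_frac_h": -0.18,
    "torso_axis_hi_frac_h": 0.20,
    "head_radius_frac_h": 0.062,
}


class ConfigurationError(ValueError):
    """A configuration table is missing a required entry."""


class InsufficientDataError(ValueError):
    """Not enough samples to estimate a quantity."""


def _rot_x(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def shoulder_rotation(flex: float, abd: float, rot: float) -> np.ndarray:
    """Rotation matrix of the shoulder ball joint (degrees).

    ``R = Rx(-flex) @ Rz(abd) @ Ry(rot)``; the sign on flexion makes positive
    flexion swing the hanging arm forward (+z).
    """
    return _rot_x(-flex) @ _rot_z(abd) @ _rot_y(rot)


def decompose_shoulder(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`shoulder_rotation`, angles in degrees.

    Near the gimbal configuration (arm pointing straight sideways) flexion is
    set to zero and the residual folds into internal rotation.
    """
    u = R @ np.array([0.0, -1.0, 0.0])  # upper-arm direction
    abd = math.degrees(math.asin(max(-1.0, min(1.0, u[0]))))
    if abs(abs(u[0]) - 1.0) < 1e-12:
        flex = 0.0
    else:
        flex = math.degrees(math.atan2(u[2], -u[1]))
    M = _rot_z(-abd) @ _rot_x(flex) @ R
    rot = math.degrees(math.atan2(M[0, 2], M[0, 0]))
    return flex, abd, rot


@dataclass(frozen=True)
class SkeletonTopology:
    """Joint set, segment tree and kinematic chains of the tracked skeleton."""

    joints: tuple[str, ...] = JOINTS
    segments: tuple[tuple[str, str, str], ...] = SEGMENTS
    end_effectors: tuple[str, ...] = END_EFFECTORS
    intermediate_joints: tuple[str, ...] = INTERMEDIATE_JOINTS
    root: str = "torso"

    def __post_init__(self):
        if len(self.joints) != 8:
            raise ValueError("upper-body topology requires exactly 8 joints")
        names = set(self.joints)
        for _, parent, child in self.segments:
            if parent not in names or child not in names:
                raise ValueError(f"segment references unknown joint: {parent}->{child}")
        if set(self.end_effectors) & set(self.intermediate_joints):
            raise ValueError("end effectors and intermediate joints must be disjoint")

    def parent_of(self, joint: str) -> str | None:
        for _, parent, child in self.segments:
            if child == joint:
                return parent
        return None

    def chain(self, joint: str) -> list[str]:
        """Ordered joint list from the root to ``joint`` (inclusive)."""
        out = [joint]
        while (p := self.parent_of(out[0])) is not None:
            out.insert(0, p)
        if out[0] != self.root:
            raise ValueError(f"{joint} not connected to {self.root}")
        return out

    def segment_length_name(self, parent: str, child: str) -> str:
        for name, p, c in self.segments:
            if (p, c) == (parent, child):
                return name
        raise KeyError((parent, child))

    def adjacent(self, seg_a: str, seg_b: str) -> bool:
        """Two segments are adjacent when they share a joint."""
        a = next(s for s in self.segments if s[0] == seg_a)
        b = next(s for s in self.segments if s[0] == seg_b)
        return len({a[1], a[2]} & {b[1], b[2]}) > 0


@dataclass
class KinematicModel:
    """Upper-body kinematic model: lengths, limits, collision proxies, stature."""

    topology: SkeletonTopology
    limb_lengths: dict[str, float]  # mm per segment name
    stature: float  # H, mm
    joint_limits: dict[str, tuple[float, float]]
    shoulder_rise: float  # mm, vertical torso->shoulder offset
    shoulder_lateral: float  # mm, lateral torso->shoulder offset
    collision_config: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COLLISION))

    def __post_init__(self):
        for name, length in self.limb_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive limb length for {name}")
        for dof, (lo, hi) in self.joint_limits.items():
            if not lo < hi:
                raise ValueError(f"degenerate limit interval for {dof}")

    # -- fixed joint placement -------------------------------------------------
    def shoulder_position(self, side: str) -> np.ndarray:
        sign = 1.0 if side == "l" else -1.0
        return np.array([sign * self.shoulder_lateral, self.shoulder_rise, 0.0])

    def head_position(self) -> np.ndarray:
        return np.array([0.0, self.limb_lengths["neck"], 0.0])

    def arm_lengths(self, side: str) -> tuple[float, float]:
        return self.limb_lengths[f"{side}_upper_arm"], self.limb_lengths[f"{side}_forearm"]

    def copy(self) -> "KinematicModel":
        return KinematicModel(
            topology=self.topology,
            limb_lengths=dict(self.limb_lengths),
            stature=self.stature,
            joint_limits=dict(self.joint_limits),
            shoulder_rise=self.shoulder_rise,
            shoulder_lateral=self.shoulder_lateral,
            collision_config=dict(self.collision_config),
        )

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stature_mm": float(self.stature),
            "shoulder_rise_mm": float(self.shoulder_rise),
            "shoulder_lateral_mm": float(self.shoulder_lateral),
            "limb_lengths_mm": {k: float(v) for k, v in self.limb_lengths.items()},
            "joint_limits_deg": {k: [float(v[0]), float(v[1])] for k, v in self.joint_limits.items()},
            "collision": {k: float(v) for k, v in self.collision_config.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "KinematicModel":
        return cls(
            topology=SkeletonTopology(),
            limb_lengths=dict(data["limb_lengths_mm"]),
            stature=float(data["stature_mm"]),
            joint_limits={k: (float(v[0]), float(v[1])) for k, v in data["joint_limits_deg"].items()},
            shoulder_rise=float(data["shoulder_rise_mm"]),
            shoulder_lateral=float(data["shoulder_lateral_mm"]),
            collision_config=dict(data.get("collision", DEFAULT_COLLISION)),
        )

    @classmethod
    def load(cls, path) -> "KinematicModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Pose:
    """A validated model pose: joint angles plus FK-consistent joint positions."""

    timestamp: float
    joint_angles: dict[str, float]  # degrees per DOF
    joint_positions: dict[str, np.ndarray]  # mm, torso-referenced

    @classmethod
    def from_angles(cls, model: KinematicModel, joint_angles: dict[str, float], timestamp: float = 0.0) -> "Pose":
        return cls(
            timestamp=timestamp,
            joint_angles=dict(joint_angles),
            joint_positions=forward_kinematics(model, joint_angles),
        )

    def position_array(self, joints=JOINTS) -> np.ndarray:
        return np.stack([self.joint_positions[j] for j in joints])

    def copy_at(self, timestamp: float) -> "Pose":
        return Pose(timestamp, dict(self.joint_angles), {k: v.copy() for k, v in self.joint_positions.items()})


def neutral_pose(model: KinematicModel, timestamp: float = 0.0) -> Pose:
    """Reference pose with both arms hanging straight down."""
    return Pose.from_angles(model, {d: 0.0 for d in DOF_NAMES}, timestamp)


def build_default_model(
    stature_h: float,
    ratio_table: dict[str, float] | None = None,
    joint_limits: dict[str, tuple[float, float]] | None = None,
    collision_config: dict[str, float] | None = None,
) -> KinematicModel:
    """Build a model whose segment lengths are anthropometric fractions of stature.

    Parameters
    ----------
    stature_h:
        Performer stature ``H`` in mm (floor to crown), in [1000, 2300].
    ratio_table:
        Per-segment fraction of ``H``; defaults to the shipped Drillis–Contini
        proportions.  Must cover every segment in the topology.
    """
    if stature_h <= 0:
        raise ValueError(f"stature must be positive, got {stature_h}")
    if not 1000.0 <= stature_h <= 2300.0:
        raise ValueError(f"stature {stature_h} mm outside plausible range [1000, 2300]")
    ratios = dict(DEFAULT_RATIOS) if ratio_table is None else dict(ratio_table)
    topo = SkeletonTopology()
    lengths = {}
    for name, _, _ in topo.segments:
        if name not in ratios:
            raise ConfigurationError(f"ratio table missing segment {name!r}")
        lengths[name] = ratios[name] * stature_h
    rise = ratios.get("shoulder_rise", DEFAULT_RATIOS["shoulder_rise"]) * stature_h
    # the clavicle ratio is the lateral half-shoulder width; the segment's
    # length is the full torso-root -> shoulder offset (lateral + rise)
    lateral = ratios["l_clavicle"] * stature_h
    for name in ("l_clavicle", "r_clavicle"):
        lengths[name] = math.hypot(ratios[name] * stature_h, rise)
    return KinematicModel(
        topology=topo,
        limb_lengths=lengths,
        stature=stature_h,
        joint_limits=dict(joint_limits or DEFAULT_JOINT_LIMITS),
        shoulder_rise=rise,
        shoulder_lateral=lateral,
        collision_config=dict(collision_config or DEFAULT_COLLISION),
    )


def estimate_stature(face_centroid_heights) -> float:
    """Stature from floor-to-eye samples: ``H = H_e / 0.936``.

    ``H_e`` is taken as the mean of the supplied face-centroid height samples
    (mm); the 0.936 factor is the eye-height fraction of stature in the
    Drillis–Contini proportions.
    """
    samples = np.asarray(list(face_centroid_heights), dtype=float)
    if samples.size == 0:
        raise InsufficientDataError("no face-centroid samples to estimate stature from")
    return float(samples.mean() / EYE_HEIGHT_RATIO)


def arm_positions(
    model: KinematicModel, side: str, flex: float, abd: float, rot: float, elbow_flex: float
) -> tuple[np.ndarray, np.ndarray]:
    """Elbow and hand positions for one arm (angles in degrees)."""
    l_ua, l_fa = model.arm_lengths(side)
    S = model.shoulder_position(side)
    R = shoulder_rotation(flex, abd, rot)
    down = np.array([0.0, -1.0, 0.0])
    elbow = S + l_ua * (R @ down)
    fore_dir = R @ (_rot_x(-elbow_flex) @ down)
    hand = elbow + l_fa * fore_dir
    return elbow, hand


def forward_kinematics(model: KinematicModel, joint_angles: dict[str, float]) -> dict[str, np.ndarray]:
    """Joint positions (mm, torso at origin) for a full set of DOF angles.

    Angles outside their limit interval are still computed; validity is the
    business of :func:`kinfilter.ik_solver.check_pose_validity`.
    """
    missing = [d for d in model.joint_limits if d not in joint_angles]
    if missing:
        raise ValueError(f"missing angles for DOFs: {missing}")
    positions: dict[str, np.ndarray] = {
        "torso": np.zeros(3),
        "head": model.head_position(),
    }
    for side in ("l", "r"):
        positions[f"{side}_shoulder"] = model.shoulder_position(side)
        elbow, hand = arm_positions(
            model,
            side,
            joint_angles[f"{side}_shoulder_flex"],
            joint_angles[f"{side}_shoulder_abd"],
            joint_angles[f"{side}_shoulder_rot"],
            joint_angles[f"{side}_elbow_flex"],
        )
        positions[f"{side}_elbow"] = elbow
        positions[f"{side}_hand"] = hand
    return positions
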