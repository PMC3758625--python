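"""Stream, pose, trajectory and configuration I/O.

Frame streams are JSONL (one object per frame:
``{"t": .., "joints": {name: {"x", "y", "z", "c"}}}``) or long-format CSV with
columns ``t, joint, x, y, z, c``.  Units are mm in the torso-referenced frame
(+y up, +z toward the camera, +x the performer's left).  Poses are written as
JSONL with joint angles and positions, or exported to BVH for animation and
biomechanics tools.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .skeleton_model import DOF_NAMES, JOINTS, KinematicModel, Pose
from .pose_filter import TrackerFrame


class SchemaError(ValueError):
    """A stream record does not match the frame schema."""


def _dialect_for(path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    s = str(path)
    if s.endswith(".jsonl") or s.endswith(".json"):
        return "jsonl"
    if s.endswith(".csv"):
        return "csv"
    raise ValueError(f"cannot infer dialect from {path!r}; pass dialect='jsonl' or 'csv'")


def write_frames(frames, path, dialect: str | None = None) -> None:
    dialect = _dialect_for(path, dialect)
    if dialect == "jsonl":
        with open(path, "w") as fh:
            for f in frames:
                rec = {
                    "t": float(f.t),
                    "joints": {
                        j: {
                            "x": float(f.positions[j][0]),
                            "y": float(f.positions[j][1]),
                            "z": float(f.positions[j][2]),
                            "c": float(f.confidence[j]),
                        }
                        for j in JOINTS
                    },
                }
                fh.write(json.dumps(rec) + "\n")
    elif dialect == "csv":
        rows = []
        for f in frames:
            for j in JOINTS:
                p = f.positions[j]
                rows.append((float(f.t), j, float(p[0]), float(p[1]), float(p[2]), float(f.confidence[j])))
        pd.DataFrame(rows, columns=["t", "joint", "x", "y", "z", "c"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_frames(path, dialect: str | None = None) -> list[TrackerFrame]:
    dialect = _dialect_for(path, dialect)
    frames: list[TrackerFrame] = []
    if dialect == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    joints = rec["joints"]
                    positions = {j: np.array([joints[j]["x"], joints[j]["y"], joints[j]["z"]], float) for j in JOINTS}
                    confidence = {j: float(joints[j]["c"]) for j in JOINTS}
                    frames.append(TrackerFrame(float(rec["t"]), positions, confidence))
                except (KeyError, ValueError, TypeError) as exc:
                    raise SchemaError(f"{path}:{lineno}: malformed frame record ({exc})") from exc
    elif dialect == "csv":
        df = pd.read_csv(path)
        required = {"t", "joint", "x", "y", "z", "c"}
        if not required.issubset(df.columns):
            raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        for t, group in df.groupby("t", sort=True):
            try:
                positions = {}
                confidence = {}
                for _, row in group.iterrows():
                    positions[row["joint"]] = np.array([row["x"], row["y"], row["z"]], float)
                    confidence[row["joint"]] = float(row["c"])
                frames.append(TrackerFrame(float(t), positions, confidence))
            except (KeyError, ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: malformed frame at t={t} ({exc})") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return frames


def write_poses(poses, path, format: str = "jsonl", model: KinematicModel | None = None, rate: float | None = None) -> None:
    """Write a pose sequence as JSONL (angles + positions) or BVH.

    BVH export requires the ``model`` (for the hierarchy offsets); the frame
    time is taken from ``rate`` or inferred from consecutive timestamps.
    """
    if format == "jsonl":
        with open(path, "w") as fh:
            for p in poses:
                rec = {
                    "t": float(p.timestamp),
                    "angles": {d: float(p.joint_angles[d]) for d in p.joint_angles},
                    "joints": {
                        j: {"x": float(v[0]), "y": float(v[1]), "z": float(v[2])}
                        for j, v in p.joint_positions.items()
                    },
                }
                fh.write(json.dumps(rec) + "\n")
    elif format == "bvh":
        if model is None:
            raise ValueError("BVH export requires the kinematic model")
        with open(path, "w") as fh:
            fh.write(bvh_document(poses, model, rate=rate))
    else:
        raise ValueError(f"unknown pose format {format!r}")


def read_poses(path) -> list[Pose]:
    poses = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                poses.append(
                    Pose(
                        timestamp=float(rec["t"]),
                        joint_angles={d: float(v) for d, v in rec["angles"].items()},
                        joint_positions={j: np.array([v["x"], v["y"], v["z"]], float) for j, v in rec["joints"].items()},
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise SchemaError(f"{path}:{lineno}: malformed pose record ({exc})") from exc
    return poses


#: BVH joint tree: (joint, children)
_BVH_TREE = ("torso", [("head", []), ("l_shoulder", [("l_elbow", [("l_hand", [])])]), ("r_shoulder", [("r_elbow", [("r_hand", [])])])])

#: channel order used for every joint
_BVH_CHANNELS = "Xrotation Zrotation Yrotation"


def _bvh_offset(model: KinematicModel, joint: str, parent: str | None) -> np.ndarray:
    from .skeleton_model import forward_kinematics

    neutral = forward_kinematics(model, {d: 0.0 for d in DOF_NAMES})
    if parent is None:
        return np.zeros(3)
    return neutral[joint] - neutral[parent]


def _bvh_rotations(pose: Pose, joint: str) -> tuple[float, float, float]:
    """Per-joint (X, Z, Y) Euler channels reproducing the model's FK."""
    a = pose.joint_angles
    if joint.endswith("shoulder"):
        side = joint[0]
        return (-a[f"{side}_shoulder_flex"], a[f"{side}_shoulder_abd"], a[f"{side}_shoulder_rot"])
    if joint.endswith("elbow"):
        side = joint[0]
        return (-a[f"{side}_elbow_flex"], 0.0, 0.0)
    return (0.0, 0.0, 0.0)


def bvh_document(poses, model: KinematicModel, rate: float | None = None) -> str:
    poses = list(poses)
    if rate is None:
        if len(poses) >= 2:
            dts = np.diff([p.timestamp for p in poses])
            frame_time = float(np.median(dts))
        else:
            frame_time = 1.0 / 30.0
    else:
        frame_time = 1.0 / rate
    lines = ["HIERARCHY"]
    order: list[str] = []

    def emit(node, parent, indent):
        joint, children = node
        pad = "  " * indent
        kw = "ROOT" if parent is None else "JOINT"
        lines.append(f"{pad}{kw} {joint}")
        lines.append(f"{pad}{{")
        off = _bvh_offset(model, joint, parent)
        lines.append(f"{pad}  OFFSET {off[0]:.4f} {off[1]:.4f} {off[2]:.4f}")
        if parent is None:
            lines.append(f"{pad}  CHANNELS 6 Xposition Yposition Zposition {_BVH_CHANNELS}")
        else:
            lines.append(f"{pad}  CHANNELS 3 {_BVH_CHANNELS}")
        order.append(joint)
        if children:
            for child in children:
                emit(child, joint, indent + 1)
        else:
            lines.append(f"{pad}  End Site")
            lines.append(f"{pad}  {{")
            lines.append(f"{pad}    OFFSET 0.0000 0.0000 0.0000")
            lines.append(f"{pad}  }}")
        lines.append(f"{pad}}}")

    emit(_BVH_TREE, None, 0)
    lines.append("MOTION")
    lines.append(f"Frames: {len(poses)}")
    lines.append(f"Frame Time: {frame_time:.6f}")
    for p in poses:
        vals = [0.0, 0.0, 0.0]  # root translation: torso is the stream origin
        for joint in order:
            vals.extend(_bvh_rotations(p, joint))
        lines.append(" ".join(f"{v:.4f}" for v in vals))
    return "\n".join(lines) + "\n"


def frames_to_trajectory(frames, joint: str) -> tuple[np.ndarray, np.ndarray]:
    """(times, positions) of one joint across a frame or pose sequence."""
    times = np.array([f.t if hasattr(f, "t") else f.timestamp for f in frames], float)
    getter = lambda f: f.positions[joint] if hasattr(f, "positions") else f.joint_positions[joint]
    return times, np.stack([np.asarray(getter(f), float) for f in frames])


def write_trajectory_csv(times, positions, path) -> None:
    pd.DataFrame({"t": times, "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2]}).to_csv(path, index=False)


def read_trajectory_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    required = {"t", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df["t"].to_numpy(float), df[["x", "y", "z"]].to_numpy(float)


def read_points(path) -> np.ndarray:
    """(n, 3) point set from a CSV with x,y,z columns or a JSON list of triples."""
    s = str(path)
    if s.endswith(".json"):
        with open(path) as fh:
            return np.asarray(json.load(fh), float).reshape(-1, 3)
    df = pd.read_csv(path)
    if not {"x", "y", "z"}.issubset(df.columns):
        raise SchemaError(f"{path}: point files need x,y,z columns")
    return df[["x", "y", "z"]].to_numpy(float)
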