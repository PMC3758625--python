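"""Two-level self-collision detection between body-segment proxies.

The broad phase compares axis-aligned bounding boxes; the narrow phase runs
only for pairs whose boxes overlap.  Segment proxies are capsules (the head is
a degenerate, zero-length capsule, i.e. a sphere), which keeps the narrow
phase exact: two capsules intersect iff the distance between their axis
segments is at most the sum of their radii.  Boundary contact counts as a
collision, so the filter errs toward keeping segments separated.

A tessellated triangle mesh of every proxy is available (``SegmentGeometry.mesh``)
for export and for auditing the conservative-AABB invariant; it is inscribed in
the analytic capsule, so the analytic AABB always contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .skeleton_model import KinematicModel, Pose


class GeometryError(ValueError):
    """A collision proxy is degenerate (non-positive radius or invalid axis)."""


def aabb_overlap(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]) -> bool:
    """Closed-interval overlap test of two axis-aligned boxes ((min, max) each)."""
    amin, amax = a
    bmin, bmax = b
    if np.any(amin > amax) or np.any(bmin > bmax):
        raise ValueError("malformed AABB: min > max on some axis")
    return bool(np.all(amin <= bmax) and np.all(bmin <= amax))


def segment_segment_distance(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2] (clamped closest points)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-18 and e <= 1e-18:
        return float(np.linalg.norm(r))
    if a <= 1e-18:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = float(d1 @ r)
        if e <= 1e-18:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = min(1.0, max(0.0, (b * f - c * e) / denom)) if denom > 1e-18 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


@dataclass
class SegmentGeometry:
    """A posed capsule proxy for one body segment, in the torso frame (mm)."""

    name: str
    p0: np.ndarray
    p1: np.ndarray
    radius: float
    joints: frozenset  # joints this body is attached to, for adjacency exclusion

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError(f"non-positive proxy radius for {self.name}")

    @property
    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.minimum(self.p0, self.p1) - self.radius
        hi = np.maximum(self.p0, self.p1) + self.radius
        return lo, hi

    @cached_property
    def mesh(self):
        """Tessellated proxy mesh (trimesh), posed in the torso frame."""
        import trimesh

        axis = self.p1 - self.p0
        length = float(np.linalg.norm(axis))
        if length < 1e-9:
            m = trimesh.creation.icosphere(subdivisions=2, radius=self.radius)
            m.apply_translation(self.p0)
            return m
        m = trimesh.creation.capsule(height=length, radius=self.radius)
        # locate the canonical axis endpoints from the mesh bounds (version-proof)
        zmin, zmax = m.bounds[0][2], m.bounds[1][2]
        a0 = np.array([0.0, 0.0, zmin + self.radius])
        z = np.array([0.0, 0.0, 1.0])
        d = axis / length
        v = np.cross(z, d)
        c = float(z @ d)
        if np.linalg.norm(v) < 1e-12:
            R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            R = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = self.p0 - R @ a0
        m.apply_transform(T)
        return m


def segment_collision(geom_a: SegmentGeometry, geom_b: SegmentGeometry, stats: dict | None = None) -> bool:
    """Two-level intersection test between two posed segment proxies.

    The narrow (capsule) test is skipped — and the pair reported separated —
    whenever the bounding boxes do not overlap.
    """
    if stats is not None:
        stats["broad_tests"] = stats.get("broad_tests", 0) + 1
    if not aabb_overlap(geom_a.aabb, geom_b.aabb):
        return False
    if stats is not None:
        stats["narrow_tests"] = stats.get("narrow_tests", 0) + 1
    dist = segment_segment_distance(geom_a.p0, geom_a.p1, geom_b.p0, geom_b.p1)
    return dist <= geom_a.radius + geom_b.radius


def build_segment_geometries(model: KinematicModel, positions: dict[str, np.ndarray]) -> list[SegmentGeometry]:
    """Collision bodies (torso trunk, head, four arm segments) posed at ``positions``."""
    cc = model.collision_config
    H = model.stature
    geoms = [
        SegmentGeometry(
            "torso",
            np.array([0.0, cc["torso_axis_lo_frac_h"] * H, 0.0]),
            np.array([0.0, cc["torso_axis_hi_frac_h"] * H, 0.0]),
            cc["torso_radius_frac_h"] * H,
            frozenset({"torso", "head", "l_shoulder", "r_shoulder"}),
        ),
        SegmentGeometry(
            "head",
            positions["head"],
            positions["head"],
            cc["head_radius_frac_h"] * H,
            frozenset({"head"}),
        ),
    ]
    for side in ("l", "r"):
        l_ua, l_fa = model.arm_lengths(side)
        geoms.append(
            SegmentGeometry(
                f"{side}_upper_arm",
                positions[f"{side}_shoulder"],
                positions[f"{side}_elbow"],
                cc["upper_arm_radius_frac"] * l_ua,
                frozenset({f"{side}_shoulder", f"{side}_elbow"}),
            )
        )
        geoms.append(
            SegmentGeometry(
                f"{side}_forearm",
                positions[f"{side}_elbow"],
                positions[f"{side}_hand"],
                cc["forearm_radius_frac"] * l_fa,
                frozenset({f"{side}_elbow", f"{side}_hand"}),
            )
        )
    return geoms


def candidate_pairs(geoms: list[SegmentGeometry]) -> list[tuple[SegmentGeometry, SegmentGeometry]]:
    """All unordered non-adjacent body pairs (adjacency = shared joint)."""
    out = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            if geoms[i].joints & geoms[j].joints:
                continue
            out.append((geoms[i], geoms[j]))
    return out


def detect_self_collisions(
    model: KinematicModel,
    pose: Pose | dict[str, np.ndarray],
    stats: dict | None = None,
) -> list[tuple[str, str]]:
    """Colliding non-adjacent segment pairs for a posed model.

    Accepts either a :class:`Pose` or a plain joint-position dict.
    """
    positions = pose.joint_positions if isinstance(pose, Pose) else pose
    geoms = build_segment_geometries(model, positions)
    hits = []
    for a, b in candidate_pairs(geoms):
        if segment_collision(a, b, stats=stats):
            hits.append((a.name, b.name))
    return hits
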