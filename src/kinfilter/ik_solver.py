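"""Analytic arm inverse kinematics with reachability clamping and pose repair.

Each arm is a 4-DOF chain (shoulder ball joint + elbow hinge).  Given the
shoulder position and a hand target, elbow flexion follows from the law of
cosines and the elbow lies on a circle around the shoulder–hand axis; the
remaining redundancy (the swivel angle on that circle) is fixed by the closest
valid candidate to the observed elbow centroid when one is available, else to
the previous pose's swivel.  Candidates violating joint limits or colliding
with the rest of the body are discarded; if none survives, the pose is
repaired by :func:`resolve_invalid_pose`, which pushes the target out of
obstacle proxies (toward the side the hand came from) and searches swivel and
reach for the valid pose whose hand is closest to the desired target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import collision as _col
from .skeleton_model import KinematicModel, Pose

#: margin (mm) kept off the inner reachability boundary to avoid singular elbows
INNER_REACH_EPS = 1.0

_DOWN = np.array([0.0, -1.0, 0.0])


@dataclass
class ValidityReport:
    """Outcome of a pose validity check; empty report means the pose is valid."""

    limit_violations: list = field(default_factory=list)  # (dof, angle, lo, hi)
    collision_pairs: list = field(default_factory=list)  # (segment, segment)

    @property
    def ok(self) -> bool:
        return not self.limit_violations and not self.collision_pairs


@dataclass
class ArmSolution:
    """One arm's solved sub-pose."""

    side: str
    angles: dict[str, float]  # the arm's 4 DOFs, degrees
    elbow: np.ndarray
    hand: np.ndarray
    swivel: float  # degrees on the elbow circle
    valid: bool
    resolved: bool = False  # True when produced by resolve_invalid_pose


def clamp_to_reachable(
    shoulder_pos: np.ndarray,
    target_pos: np.ndarray,
    l_upper: float,
    l_fore: float,
    epsilon: float = INNER_REACH_EPS,
    fallback_dir: np.ndarray | None = None,
) -> np.ndarray:
    """Project a hand target into the arm's reachability annulus.

    Targets beyond full extension are pulled back to the outer sphere along the
    shoulder→target ray; targets inside ``|l_upper - l_fore| + epsilon`` are
    pushed out to that inner bound.  A target coincident with the shoulder has
    no direction: ``fallback_dir`` (e.g. the previous frame's hand direction)
    is used, defaulting to the hanging-arm direction.
    """
    if l_upper <= 0 or l_fore <= 0:
        raise ValueError("limb lengths must be positive")
    shoulder_pos = np.asarray(shoulder_pos, float)
    target_pos = np.asarray(target_pos, float)
    v = target_pos - shoulder_pos
    d = float(np.linalg.norm(v))
    inner = abs(l_upper - l_fore)
    inner_bound = inner + epsilon if inner > 0 else (epsilon if d < 1e-9 else 0.0)
    outer = l_upper + l_fore
    if d < 1e-9:
        direction = _DOWN if fallback_dir is None else np.asarray(fallback_dir, float)
        n = np.linalg.norm(direction)
        direction = _DOWN if n < 1e-9 else direction / n
        return shoulder_pos + max(inner_bound, epsilon) * direction
    direction = v / d
    if d > outer:
        return shoulder_pos + outer * direction
    if d < inner + epsilon and inner > 0:
        return shoulder_pos + (inner + epsilon) * direction
    return target_pos


def _swivel_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the plane normal to the shoulder→hand axis.

    The reference direction is global "down" so that swivel 0 is the natural
    elbow-under-the-axis configuration; near-vertical axes fall back to -z.
    """
    ref = _DOWN if abs(float(u @ _DOWN)) < 0.999 else np.array([0.0, 0.0, -1.0])
    n1 = ref - (ref @ u) * u
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(u, n1)
    return n1, n2


def elbow_circle(
    shoulder: np.ndarray, hand: np.ndarray, l_upper: float, l_fore: float
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, np.ndarray]:
    """Center, radius and in-plane basis of the reachable-elbow circle."""
    v = hand - shoulder
    d = float(np.linalg.norm(v))
    u = v / d
    cos_alpha = (l_upper**2 + d**2 - l_fore**2) / (2.0 * l_upper * d)
    cos_alpha = max(-1.0, min(1.0, cos_alpha))
    center = shoulder + l_upper * cos_alpha * u
    radius = l_upper * math.sqrt(max(0.0, 1.0 - cos_alpha**2))
    n1, n2 = _swivel_basis(u)
    return center, radius, u, n1, n2


def angles_from_elbow_hand(
    side: str,
    shoulder: np.ndarray,
    elbow: np.ndarray,
    hand: np.ndarray,
    rot_hint: float = 0.0,
) -> dict[str, float]:
    """Exact joint angles reproducing the given shoulder/elbow/hand layout.

    For a straight arm the internal-rotation DOF is unobservable from
    positions; ``rot_hint`` fills it.
    """
    ux, uy, uz = float(elbow[0] - shoulder[0]), float(elbow[1] - shoulder[1]), float(elbow[2] - shoulder[2])
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    fx, fy, fz = float(hand[0] - elbow[0]), float(hand[1] - elbow[1]), float(hand[2] - elbow[2])
    fn = math.sqrt(fx * fx + fy * fy + fz * fz)
    fx, fy, fz = fx / fn, fy / fn, fz / fn
    cos_t = max(-1.0, min(1.0, ux * fx + uy * fy + uz * fz))
    theta = math.degrees(math.acos(cos_t))
    px, py, pz = fx - cos_t * ux, fy - cos_t * uy, fz - cos_t * uz
    pn = math.sqrt(px * px + py * py + pz * pz)
    abd = math.degrees(math.asin(max(-1.0, min(1.0, ux))))
    if abs(abs(ux) - 1.0) < 1e-12:
        flex = 0.0
    else:
        flex = math.degrees(math.atan2(uz, -uy))
    if pn < 1e-9:
        rot = rot_hint
    else:
        px, py, pz = px / pn, py / pn, pz / pn
        # rot from the residual after removing flexion and abduction:
        # R = [cross(-u, p) | -u | p]; M = Rz(-abd) Rx(flex) R; rot = atan2(M02, M00)
        cxx, cxy, cxz = -(uy * pz - uz * py), -(uz * px - ux * pz), -(ux * py - uy * px)
        cf, sf = math.cos(math.radians(flex)), math.sin(math.radians(flex))
        ca, sa = math.cos(math.radians(abd)), math.sin(math.radians(abd))
        # row 0 of Rz(-abd) Rx(flex) = (ca, sa*cf, -sa*sf) applied to columns of R
        r0x = ca * cxx + sa * (cf * cxy - sf * cxz)
        r0z = ca * px + sa * (cf * py - sf * pz)
        rot = math.degrees(math.atan2(r0z, r0x))
    return {
        f"{side}_shoulder_flex": flex,
        f"{side}_shoulder_abd": abd,
        f"{side}_shoulder_rot": rot,
        f"{side}_elbow_flex": theta,
    }


def _arm_fk(side: str, shoulder: np.ndarray, angles: dict[str, float], l_upper: float, l_fore: float):
    """Scalar-trig arm FK (matches skeleton_model.arm_positions; hot path)."""
    f = math.radians(angles[f"{side}_shoulder_flex"])
    a = math.radians(angles[f"{side}_shoulder_abd"])
    r = math.radians(angles[f"{side}_shoulder_rot"])
    t = math.radians(angles[f"{side}_elbow_flex"])
    cf, sf = math.cos(f), math.sin(f)
    ca, sa = math.cos(a), math.sin(a)
    cr, sr = math.cos(r), math.sin(r)
    ct, st = math.cos(t), math.sin(t)
    # upper-arm direction u = R @ (0,-1,0) with R = Rx(-flex) Rz(abd) Ry(rot)
    u = np.array([sa, -ca * cf, ca * sf])
    # local z-axis image R @ (0,0,1), needed for the elbow hinge plane
    ez = np.array([ca * sr, cf * sa * sr + sf * cr, -sf * sa * sr + cf * cr])
    elbow = shoulder + l_upper * u
    fore = ct * u + st * ez
    return elbow, elbow + l_fore * fore


def _angles_vec(S: np.ndarray, E: np.ndarray, W: np.ndarray, rot_hint: float):
    """Vectorized :func:`angles_from_elbow_hand` over n elbow/hand rows.

    Returns (flex, abd, rot, theta) arrays in degrees.
    """
    u = E - S
    un = np.linalg.norm(u, axis=1)
    u = u / un[:, None]
    f = W - E
    fn = np.linalg.norm(f, axis=1)
    f = f / fn[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", u, f), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    p = f - cos_t[:, None] * u
    pn = np.linalg.norm(p, axis=1)
    abd = np.degrees(np.arcsin(np.clip(u[:, 0], -1.0, 1.0)))
    flex = np.where(np.abs(np.abs(u[:, 0]) - 1.0) < 1e-12, 0.0, np.degrees(np.arctan2(u[:, 2], -u[:, 1])))
    safe = pn > 1e-9
    p_hat = np.where(safe[:, None], p / np.where(pn[:, None] < 1e-30, 1.0, pn[:, None]), 0.0)
    c = np.cross(-u, p_hat)
    fr = np.radians(flex)
    ar = np.radians(abd)
    cf, sf = np.cos(fr), np.sin(fr)
    ca, sa = np.cos(ar), np.sin(ar)
    r0x = ca * c[:, 0] + sa * (cf * c[:, 1] - sf * c[:, 2])
    r0z = ca * p_hat[:, 0] + sa * (cf * p_hat[:, 1] - sf * p_hat[:, 2])
    rot = np.where(safe, np.degrees(np.arctan2(r0z, r0x)), rot_hint)
    return flex, abd, rot, theta


def _fk_vec(S: np.ndarray, flex, abd, rot, theta, l_upper: float, l_fore: float):
    """Vectorized arm FK from angle arrays (degrees) -> (elbow, hand) arrays."""
    fr, ar, rr, tr = np.radians(flex), np.radians(abd), np.radians(rot), np.radians(theta)
    cf, sf = np.cos(fr), np.sin(fr)
    ca, sa = np.cos(ar), np.sin(ar)
    cr, sr = np.cos(rr), np.sin(rr)
    ct, st = np.cos(tr), np.sin(tr)
    u = np.stack([sa, -ca * cf, ca * sf], axis=1)
    ez = np.stack([ca * sr, cf * sa * sr + sf * cr, -sf * sa * sr + cf * cr], axis=1)
    elbow = S + l_upper * u
    hand = elbow + l_fore * (ct[:, None] * u + st[:, None] * ez)
    return elbow, hand


def _seg_dist_vec(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Distances between n segments [p1,q1] and one fixed segment [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = float(d2 @ d2)
    f = r @ d2
    c = np.einsum("ij,ij->i", d1, r)
    a_safe = np.where(a < 1e-18, 1.0, a)
    if e < 1e-18:
        s = np.clip(-c / a_safe, 0.0, 1.0)
        t = np.zeros_like(s)
    else:
        b = d1 @ d2
        denom = a * e - b * b
        s = np.where(denom > 1e-18, np.clip((b * f - c * e) / np.where(denom < 1e-30, 1.0, denom), 0.0, 1.0), 0.0)
        t = (b * s + f) / e
        low, high = t < 0.0, t > 1.0
        t = np.clip(t, 0.0, 1.0)
        s = np.where(low, np.clip(-c / a_safe, 0.0, 1.0), s)
        s = np.where(high, np.clip((b - c) / a_safe, 0.0, 1.0), s)
    s = np.where(a < 1e-18, 0.0, s)
    closest1 = p1 + s[:, None] * d1
    closest2 = p2 + t[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


def _collide_vec(model, side: str, S: np.ndarray, E: np.ndarray, W: np.ndarray, obstacles) -> np.ndarray:
    """Boolean mask over n candidate arms: does any segment hit any obstacle?"""
    cc = model.collision_config
    l_ua, l_fa = model.arm_lengths(side)
    r_ua = cc["upper_arm_radius_frac"] * l_ua
    r_fa = cc["forearm_radius_frac"] * l_fa
    n = E.shape[0]
    Sb = np.broadcast_to(S, (n, 3))
    hit = np.zeros(n, dtype=bool)
    arm_joints = (
        (Sb, E, r_ua, frozenset({f"{side}_shoulder", f"{side}_elbow"})),
        (E, W, r_fa, frozenset({f"{side}_elbow", f"{side}_hand"})),
    )
    for p1, q1, r, joints in arm_joints:
        for ob in obstacles:
            if joints & ob.joints:
                continue
            hit |= _seg_dist_vec(p1, q1, ob.p0, ob.p1) <= r + ob.radius
    return hit


def _limits_mask(model, side: str, flex, abd, rot, theta) -> np.ndarray:
    ok = np.ones(flex.shape[0], dtype=bool)
    for name, arr in (
        (f"{side}_shoulder_flex", flex),
        (f"{side}_shoulder_abd", abd),
        (f"{side}_shoulder_rot", rot),
        (f"{side}_elbow_flex", theta),
    ):
        lo, hi = model.joint_limits[name]
        ok &= (arr >= lo - 1e-9) & (arr <= hi + 1e-9)
    return ok


def _limits_ok(model: KinematicModel, angles: dict[str, float]) -> bool:
    for dof, val in angles.items():
        lo, hi = model.joint_limits[dof]
        if not lo - 1e-9 <= val <= hi + 1e-9:
            return False
    return True


def _arm_geoms(model: KinematicModel, side: str, shoulder, elbow, hand) -> list[_col.SegmentGeometry]:
    cc = model.collision_config
    l_ua, l_fa = model.arm_lengths(side)
    return [
        _col.SegmentGeometry(
            f"{side}_upper_arm", shoulder, elbow, cc["upper_arm_radius_frac"] * l_ua,
            frozenset({f"{side}_shoulder", f"{side}_elbow"}),
        ),
        _col.SegmentGeometry(
            f"{side}_forearm", elbow, hand, cc["forearm_radius_frac"] * l_fa,
            frozenset({f"{side}_elbow", f"{side}_hand"}),
        ),
    ]


def static_obstacles(model: KinematicModel) -> list[_col.SegmentGeometry]:
    """Torso trunk and head proxies (pose-independent in the torso frame)."""
    positions = {"head": model.head_position()}
    geoms = _col.build_segment_geometries(
        model,
        {
            "head": positions["head"],
            "l_shoulder": model.shoulder_position("l"),
            "r_shoulder": model.shoulder_position("r"),
            "l_elbow": np.zeros(3), "r_elbow": np.zeros(3),
            "l_hand": np.zeros(3), "r_hand": np.zeros(3),
        },
    )
    return [g for g in geoms if g.name in ("torso", "head")]


def _arm_collides(model, side, shoulder, elbow, hand, obstacles) -> bool:
    """Lean capsule test of one arm against obstacle proxies (hot path of the solver)."""
    cc = model.collision_config
    l_ua, l_fa = model.arm_lengths(side)
    segs = (
        (shoulder, elbow, cc["upper_arm_radius_frac"] * l_ua, frozenset({f"{side}_shoulder", f"{side}_elbow"})),
        (elbow, hand, cc["forearm_radius_frac"] * l_fa, frozenset({f"{side}_elbow", f"{side}_hand"})),
    )
    for p0, p1, r, joints in segs:
        mid = 0.5 * (p0 + p1)
        half = 0.5 * float(np.linalg.norm(p1 - p0))
        for ob in obstacles:
            if joints & ob.joints:
                continue
            # bounding-sphere reject before the exact segment distance
            ob_mid = 0.5 * (ob.p0 + ob.p1)
            reach = half + 0.5 * float(np.linalg.norm(ob.p1 - ob.p0)) + r + ob.radius
            if float(np.linalg.norm(mid - ob_mid)) > reach:
                continue
            if _col.segment_segment_distance(p0, p1, ob.p0, ob.p1) <= r + ob.radius:
                return True
    return False


def _prev_arm_state(side: str, previous_pose: Pose | None):
    if previous_pose is None:
        return None, None, 0.0
    prev_elbow = previous_pose.joint_positions.get(f"{side}_elbow")
    prev_hand = previous_pose.joint_positions.get(f"{side}_hand")
    rot_hint = previous_pose.joint_angles.get(f"{side}_shoulder_rot", 0.0)
    return prev_elbow, prev_hand, rot_hint


def solve_arm_ik(
    model: KinematicModel,
    side: str,
    shoulder_pos: np.ndarray,
    hand_target: np.ndarray,
    previous_pose: Pose | None = None,
    elbow_hint: np.ndarray | None = None,
    obstacles: list[_col.SegmentGeometry] | None = None,
    swivel_samples: int = 64,
) -> ArmSolution:
    """Analytic IK for one arm; ``valid`` is False when no candidate satisfies limits.

    ``hand_target`` must already lie in the reachability annulus (see
    :func:`clamp_to_reachable`).  ``elbow_hint`` — typically the gated elbow
    centroid — selects the swivel whose elbow is closest to it; without a hint
    the swivel closest to the previous pose is kept.  ``obstacles`` are
    collision proxies the arm must not intersect (default: torso and head).
    """
    shoulder_pos = np.asarray(shoulder_pos, float)
    hand_target = np.asarray(hand_target, float)
    l_ua, l_fa = model.arm_lengths(side)
    if obstacles is None:
        obstacles = static_obstacles(model)
    center, radius, u, n1, n2 = elbow_circle(shoulder_pos, hand_target, l_ua, l_fa)
    prev_elbow, _, rot_hint = _prev_arm_state(side, previous_pose)

    def swivel_of(point: np.ndarray) -> float:
        w = point - center
        return math.degrees(math.atan2(float(w @ n2), float(w @ n1)))

    prev_swivel = swivel_of(prev_elbow) if prev_elbow is not None and radius > 1e-9 else 0.0

    if radius <= 1e-9:
        # straight (or fully folded) arm: elbow forced onto the axis
        elbow = center
        angles = angles_from_elbow_hand(side, shoulder_pos, elbow, hand_target, rot_hint=rot_hint)
        ok = _limits_ok(model, angles) and not _arm_collides(model, side, shoulder_pos, elbow, hand_target, obstacles)
        return ArmSolution(side, angles, elbow, hand_target.copy(), 0.0, ok)

    candidates: list[float] = []
    if elbow_hint is not None:
        candidates.append(swivel_of(np.asarray(elbow_hint, float)))
    if prev_elbow is not None:
        candidates.append(prev_swivel)
    candidates.append(0.0)
    grid = [-180.0 + k * 360.0 / swivel_samples for k in range(swivel_samples)]

    def evaluate(phi: float):
        e = center + radius * (math.cos(math.radians(phi)) * n1 + math.sin(math.radians(phi)) * n2)
        angles = angles_from_elbow_hand(side, shoulder_pos, e, hand_target, rot_hint=rot_hint)
        if not _limits_ok(model, angles):
            return None
        if _arm_collides(model, side, shoulder_pos, e, hand_target, obstacles):
            return None
        return e, angles

    # fast path: preferred candidates in order
    for phi in candidates:
        res = evaluate(phi)
        if res is not None:
            e, angles = res
            return ArmSolution(side, angles, e, hand_target.copy(), phi, True)

    # full swivel sweep (vectorized), keep the best-scoring valid candidate
    hint = np.asarray(elbow_hint, float) if elbow_hint is not None else None
    phis = np.asarray(grid)
    pr = np.radians(phis)
    E = center + radius * (np.cos(pr)[:, None] * n1 + np.sin(pr)[:, None] * n2)
    W = np.broadcast_to(hand_target, E.shape)
    flex, abd, rot, theta = _angles_vec(shoulder_pos, E, W, rot_hint)
    ok = _limits_mask(model, side, flex, abd, rot, theta)
    if ok.any():
        idx_ok = np.flatnonzero(ok)
        hit = _collide_vec(model, side, shoulder_pos, E[idx_ok], W[idx_ok], obstacles)
        idx_ok = idx_ok[~hit]
        if idx_ok.size:
            dphi = np.abs((phis[idx_ok] - prev_swivel + 180.0) % 360.0 - 180.0)
            if hint is not None:
                score = np.linalg.norm(E[idx_ok] - hint, axis=1)
            else:
                score = dphi
            order = np.lexsort((idx_ok, dphi, score))
            j = idx_ok[order[0]]
            angles = {
                f"{side}_shoulder_flex": float(flex[j]),
                f"{side}_shoulder_abd": float(abd[j]),
                f"{side}_shoulder_rot": float(rot[j]),
                f"{side}_elbow_flex": float(theta[j]),
            }
            return ArmSolution(side, angles, E[j], hand_target.copy(), float(phis[j]), True)

    # no limit/collision-satisfying swivel at this hand target
    angles = angles_from_elbow_hand(
        side, shoulder_pos, center + radius * n1, hand_target, rot_hint=rot_hint
    )
    return ArmSolution(side, angles, center + radius * n1, hand_target.copy(), 0.0, False)


def check_pose_validity(model: KinematicModel, pose: Pose, stats: dict | None = None) -> ValidityReport:
    """Joint-limit and self-collision audit of a full pose."""
    report = ValidityReport()
    for dof, val in pose.joint_angles.items():
        lo, hi = model.joint_limits[dof]
        if not lo - 1e-6 <= val <= hi + 1e-6:
            report.limit_violations.append((dof, val, lo, hi))
    report.collision_pairs = _col.detect_self_collisions(model, pose, stats=stats)
    return report


def _push_out_of_obstacles(
    target: np.ndarray,
    obstacles: list[_col.SegmentGeometry],
    clearance: float,
    toward: np.ndarray | None,
) -> np.ndarray:
    """Move a point out of any inflated obstacle capsule it penetrates.

    The exit direction is chosen toward ``toward`` (e.g. the previous hand
    position), which preserves which side of the body the hand stays on — a
    hand occluded behind the head or torso is kept behind it rather than
    teleported to the camera-facing side.
    """
    t = np.asarray(target, float).copy()
    for _ in range(4):  # a few rounds in case pushing out of one body enters another
        moved = False
        for ob in obstacles:
            # closest point on the obstacle axis
            axis = ob.p1 - ob.p0
            aa = float(axis @ axis)
            s = 0.0 if aa < 1e-12 else min(1.0, max(0.0, float((t - ob.p0) @ axis) / aa))
            cp = ob.p0 + s * axis
            limit = ob.radius + clearance
            d = float(np.linalg.norm(t - cp))
            if d >= limit:
                continue
            direction = None
            if toward is not None:
                cand = toward - cp
                if aa > 1e-12:
                    cand = cand - (float(cand @ axis) / aa) * axis
                n = float(np.linalg.norm(cand))
                if n > 1e-6:
                    direction = cand / n
            if direction is None:
                direction = (t - cp) / d if d > 1e-9 else np.array([0.0, 0.0, -1.0])
            # overshoot the surface a little so the forearm has room to approach
            t = cp + (ob.radius + 1.25 * clearance) * direction
            moved = True
        if not moved:
            break
    return t


def resolve_invalid_pose(
    model: KinematicModel,
    side: str,
    shoulder_pos: np.ndarray,
    hand_target: np.ndarray,
    previous_pose: Pose | None = None,
    obstacles: list[_col.SegmentGeometry] | None = None,
    swivel_samples: int = 32,
    radial_samples: int = 10,
) -> ArmSolution:
    """Closest valid alternative when the desired hand target admits no valid pose.

    Strategy: (1) push the target out of penetrated obstacle proxies toward the
    previous hand position and retry the analytic solve; (2) sweep reach
    distance x swivel with per-DOF limit clamping, scoring candidates by hand
    distance to the desired target; (3) fall back to the previous arm pose,
    then the neutral hanging arm, which is valid by construction.
    """
    shoulder_pos = np.asarray(shoulder_pos, float)
    hand_target = np.asarray(hand_target, float)
    l_ua, l_fa = model.arm_lengths(side)
    if obstacles is None:
        obstacles = static_obstacles(model)
    prev_elbow, prev_hand, rot_hint = _prev_arm_state(side, previous_pose)
    clearance = model.collision_config["forearm_radius_frac"] * l_fa

    def finish(elbow, hand, angles, swivel=0.0):
        return ArmSolution(side, angles, elbow, hand, swivel, True, resolved=True)

    # (1) obstacle push-out, preserving the approach side
    aim = hand_target
    pushed = _push_out_of_obstacles(hand_target, obstacles, clearance, prev_hand)
    if np.linalg.norm(pushed - hand_target) > 1e-9:
        aim = pushed  # keep later candidates on the approach side of the obstacle
        pushed = clamp_to_reachable(shoulder_pos, pushed, l_ua, l_fa, fallback_dir=prev_hand)
        sol = solve_arm_ik(
            model, side, shoulder_pos, pushed,
            previous_pose=previous_pose, elbow_hint=prev_elbow, obstacles=obstacles,
        )
        if sol.valid:
            sol.resolved = True
            return sol

    # (2) reach x swivel sweep with limit clamping, along the ray toward the
    # (possibly pushed) aim point; candidates scored against the true target
    v = aim - shoulder_pos
    d_t = float(np.linalg.norm(v))
    u = v / d_t if d_t > 1e-9 else _DOWN
    d_min = abs(l_ua - l_fa) + INNER_REACH_EPS
    d_max = l_ua + l_fa
    dists = np.linspace(d_min, d_max, radial_samples)
    gaps = np.abs(dists - min(max(d_t, d_min), d_max))
    order = np.argsort(gaps)
    best = None
    for di in order:
        if aim is hand_target and best is not None and best[0] <= gaps[di] + 1e-9:
            # every unclamped candidate on this (and any farther) ring scores
            # exactly its radial gap; the current best cannot be improved much
            break
        d = dists[di]
        w = shoulder_pos + d * u
        center, radius, axis_u, n1, n2 = elbow_circle(shoulder_pos, w, l_ua, l_fa)
        if radius <= 1e-9:
            phis = np.array([0.0])
            E = center[None, :]
        else:
            phis = -180.0 + np.arange(swivel_samples) * 360.0 / swivel_samples
            pr = np.radians(phis)
            E = center + radius * (np.cos(pr)[:, None] * n1 + np.sin(pr)[:, None] * n2)
        W = np.broadcast_to(w, E.shape)
        flex, abd, rot, theta = _angles_vec(shoulder_pos, E, W, rot_hint)
        limits = [model.joint_limits[f"{side}_shoulder_flex"], model.joint_limits[f"{side}_shoulder_abd"],
                  model.joint_limits[f"{side}_shoulder_rot"], model.joint_limits[f"{side}_elbow_flex"]]
        cl = [np.clip(arr, lo, hi) for arr, (lo, hi) in zip((flex, abd, rot, theta), limits)]
        changed = np.any([np.abs(a - b) > 1e-12 for a, b in zip((flex, abd, rot, theta), cl)], axis=0)
        Ec = E.copy()
        Wc = np.array(W)
        if changed.any():
            idx = np.flatnonzero(changed)
            e2, w2 = _fk_vec(shoulder_pos, cl[0][idx], cl[1][idx], cl[2][idx], cl[3][idx], l_ua, l_fa)
            Ec[idx] = e2
            Wc[idx] = w2
        hit = _collide_vec(model, side, shoulder_pos, Ec, Wc, obstacles)
        if (~hit).any():
            idx_ok = np.flatnonzero(~hit)
            score = np.linalg.norm(Wc[idx_ok] - hand_target, axis=1)
            jloc = int(np.argmin(score))
            j = idx_ok[jloc]
            sc = float(score[jloc])
            if best is None or sc < best[0] - 1e-9:
                clamped = {
                    f"{side}_shoulder_flex": float(cl[0][j]),
                    f"{side}_shoulder_abd": float(cl[1][j]),
                    f"{side}_shoulder_rot": float(cl[2][j]),
                    f"{side}_elbow_flex": float(cl[3][j]),
                }
                best = (sc, clamped, Ec[j].copy(), Wc[j].copy(), float(phis[j]))
        if best is not None and best[0] < 1e-6:
            break
    if best is not None:
        _, angles, elbow, hand, phi = best
        return finish(elbow, hand, angles, phi)

    # (3) previous arm pose, then neutral
    if prev_elbow is not None and prev_hand is not None:
        angles = angles_from_elbow_hand(side, shoulder_pos, prev_elbow, prev_hand, rot_hint=rot_hint)
        if _limits_ok(model, angles):
            elbow_c, hand_c = _arm_fk(side, shoulder_pos, angles, l_ua, l_fa)
            if not _arm_collides(model, side, shoulder_pos, elbow_c, hand_c, obstacles):
                return finish(elbow_c, hand_c, angles)
    neutral = {
        f"{side}_shoulder_flex": 0.0,
        f"{side}_shoulder_abd": 0.0,
        f"{side}_shoulder_rot": 0.0,
        f"{side}_elbow_flex": 0.0,
    }
    elbow_c, hand_c = _arm_fk(side, shoulder_pos, neutral, l_ua, l_fa)
    return finish(elbow_c, hand_c, neutral)


def solve_arm(
    model: KinematicModel,
    side: str,
    shoulder_pos: np.ndarray,
    hand_target: np.ndarray,
    previous_pose: Pose | None = None,
    elbow_hint: np.ndarray | None = None,
    obstacles: list[_col.SegmentGeometry] | None = None,
) -> ArmSolution:
    """Clamp → analytic solve → repair: always returns a valid arm sub-pose."""
    l_ua, l_fa = model.arm_lengths(side)
    _, prev_hand, _ = _prev_arm_state(side, previous_pose)
    fallback = None if prev_hand is None else prev_hand - np.asarray(shoulder_pos, float)
    clamped = clamp_to_reachable(shoulder_pos, hand_target, l_ua, l_fa, fallback_dir=fallback)
    sol = solve_arm_ik(
        model, side, shoulder_pos, clamped,
        previous_pose=previous_pose, elbow_hint=elbow_hint, obstacles=obstacles,
    )
    if sol.valid:
        return sol
    return resolve_invalid_pose(
        model, side, shoulder_pos, hand_target,
        previous_pose=previous_pose, obstacles=obstacles,
    )
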