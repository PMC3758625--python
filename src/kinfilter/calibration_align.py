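"""Cross-system trajectory comparison: rigid calibration, resampling, alignment, errors.

To compare a depth-tracker trajectory against a reference capture system the
two streams must share a coordinate frame, a sampling rate and a time origin:

* a 4-point correspondence yields the block transform ``RT = B A^{-1}``
  (``literal`` mode — exact but not orthogonality-constrained) or the
  least-squares orthogonal transform (``rigid`` mode, Kabsch; default),
* trajectories are oversampled with cubic splines to a common rate,
* the residual time offset is found per joint as the peak of the normalized
  cross-correlation, and the candidate lag (hand, elbow or shoulder) that
  maximizes the mean correlation across all three joints is applied,
* instantaneous error is then the per-frame Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline


class SingularSystemError(np.linalg.LinAlgError):
    """The correspondence points are degenerate for the requested mode."""


@dataclass
class RigidTransform:
    """Block transform y = R x + T between two capture coordinate systems (mm)."""

    R: np.ndarray  # 3x3
    T: np.ndarray  # 3

    def inverse(self) -> "RigidTransform":
        Rinv = np.linalg.inv(self.R)
        return RigidTransform(Rinv, -Rinv @ self.T)

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.T
        return M


@dataclass
class AlignmentResult:
    """Consensus temporal alignment of hand/elbow/shoulder trajectory pairs."""

    candidate_lags: dict[str, int]  # per-joint cross-correlation peak, samples
    chosen_lag: int
    mean_correlation: float


def solve_correspondence_transform(A: np.ndarray, B: np.ndarray, mode: str = "rigid") -> RigidTransform:
    """Transform mapping point set A onto point set B.

    ``literal`` solves the homogeneous system ``RT = B A^{-1}`` exactly from 4
    correspondences (requires non-coplanar points; the block is not forced to
    be a rotation, so marker noise leaks into shear).  ``rigid`` returns the
    least-squares orthogonal transform (SVD/Kabsch), usable with >= 3
    non-collinear points and robust to noise.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.shape[1] != 3:
        raise ValueError("A and B must be matching (n, 3) point sets")
    if mode == "literal":
        if A.shape[0] != 4:
            raise ValueError("literal mode requires exactly 4 correspondences")
        Ah = np.vstack([A.T, np.ones(4)])  # 4x4, columns are homogeneous points
        Bh = np.vstack([B.T, np.ones(4)])
        if abs(np.linalg.det(Ah)) < 1e-9 * max(1.0, float(np.abs(Ah).max()) ** 3):
            raise SingularSystemError(
                "the 4 source points are coplanar: the homogeneous system is singular in literal mode"
            )
        M = Bh @ np.linalg.inv(Ah)
        return RigidTransform(M[:3, :3].copy(), M[:3, 3].copy())
    if mode == "rigid":
        if A.shape[0] < 3:
            raise ValueError("rigid mode requires at least 3 correspondences")
        ca, cb = A.mean(axis=0), B.mean(axis=0)
        H = (A - ca).T @ (B - cb)
        U, S, Vt = np.linalg.svd(H)
        if S[1] < 1e-9 * max(S[0], 1.0):
            raise SingularSystemError("correspondence points are collinear; rotation is underdetermined")
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
        R = Vt.T @ D @ U.T
        return RigidTransform(R, cb - R @ ca)
    raise ValueError(f"unknown mode {mode!r}")


def apply_transform(X: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply y = R x + T to one point or an (n, 3) array."""
    pts = np.asarray(points, float)
    return pts @ X.R.T + X.T


def resample_trajectory(
    times: np.ndarray, positions: np.ndarray, target_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of a timestamped 3D trajectory to a uniform rate.

    Returns (new_times, new_positions) spanning the original time range; knots
    that coincide with new sample times are reproduced exactly.
    """
    times = np.asarray(times, float)
    positions = np.asarray(positions, float)
    if times.size < 4:
        raise ValueError("need at least 4 samples for cubic resampling")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    n = int(np.floor((times[-1] - times[0]) * target_rate)) + 1
    new_times = times[0] + np.arange(n) / target_rate
    spline = CubicSpline(times, positions, axis=0)
    return new_times, spline(new_times)


def _norm_xcorr_at_lag(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Mean per-axis Pearson correlation of a[t] with b[t + lag] on the overlap."""
    n = min(a.shape[0], b.shape[0])
    a, b = a[:n], b[:n]
    if lag >= 0:
        sa, sb = a[: n - lag], b[lag:]
    else:
        sa, sb = a[-lag:], b[: n + lag]
    if sa.shape[0] < 3:
        return -np.inf
    cors = []
    for ax in range(a.shape[1]):
        x, y = sa[:, ax], sb[:, ax]
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            continue
        cors.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(cors)) if cors else -np.inf


def temporal_align(
    trajs_a: dict[str, np.ndarray],
    trajs_b: dict[str, np.ndarray],
    max_lag: int | None = None,
    rate: float = 60.0,
    max_lag_seconds: float = 2.0,
) -> AlignmentResult:
    """Consensus lag between two trajectory sets (same joints, same rate).

    A positive lag means stream B is delayed by that many samples relative to
    A.  Per joint, the lag maximizing the normalized per-axis cross-correlation
    is a candidate; the candidate that maximizes the mean correlation applied
    simultaneously to all joints wins; ties break toward smaller ``|lag|``.
    Flat (zero-variance) trajectories are excluded from the candidate set.
    """
    joints = [j for j in trajs_a if j in trajs_b]
    if not joints:
        raise ValueError("no common joints to align")
    if max_lag is None:
        max_lag = int(round(max_lag_seconds * rate))
    lags = range(-max_lag, max_lag + 1)
    candidates: dict[str, int] = {}
    for j in joints:
        a, b = np.asarray(trajs_a[j], float), np.asarray(trajs_b[j], float)
        if a.std(axis=0).max() < 1e-12 or b.std(axis=0).max() < 1e-12:
            continue  # flat trajectory carries no timing information
        scores = [( _norm_xcorr_at_lag(a, b, lag), -abs(lag), lag) for lag in lags]
        best = max(scores)
        candidates[j] = best[2]
    if not candidates:
        raise ValueError("all trajectories are flat; alignment is undefined")

    def mean_corr(lag: int) -> float:
        vals = [_norm_xcorr_at_lag(np.asarray(trajs_a[j], float), np.asarray(trajs_b[j], float), lag) for j in joints]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else -np.inf

    scored = [(mean_corr(lag), -abs(lag), lag) for lag in set(candidates.values())]
    best_score, _, chosen = max(scored)
    return AlignmentResult(candidate_lags=candidates, chosen_lag=chosen, mean_correlation=best_score)


def shift_by_lag(traj_a: np.ndarray, traj_b: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Crop two equal-rate trajectories to their overlap after applying ``lag``."""
    a, b = np.asarray(traj_a, float), np.asarray(traj_b, float)
    n = min(a.shape[0], b.shape[0])
    a, b = a[:n], b[:n]
    if lag >= 0:
        return a[: n - lag], b[lag:]
    return a[-lag:], b[: n + lag]


def trajectory_error(traj_a: np.ndarray, traj_b: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-frame Euclidean distances plus their mean and population SD."""
    a, b = np.asarray(traj_a, float), np.asarray(traj_b, float)
    if a.shape != b.shape:
        raise ValueError(f"trajectory length/shape mismatch: {a.shape} vs {b.shape}")
    dists = np.linalg.norm(a - b, axis=1)
    return dists, float(dists.mean()), float(dists.std())
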