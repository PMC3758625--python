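"""Online limb-length estimation from raw tracker centroids.

Instantaneous limb lengths — distances between the raw centroids of a
segment's ending joints — are noisy and occasionally wild (objects in the
hand, hijacked depths).  A time-varying-coefficient running average
``l̄_k = l̄_{k-1} + (l_k - l̄_{k-1})/k`` turns them into stable estimates in
three phases: *initialization* (no samples yet, model lengths come from the
anthropometric priors), *learning* (first ``N`` accepted samples, during which
the estimate equals the arithmetic mean of those samples exactly), and
*fixation* (the estimate freezes unless the disparity between estimate and
instant length exceeds ``MaxDist``, in which case the sample counter resets
and learning restarts — the performer's apparent proportions changed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: limbs whose lengths are learned online, with their ending joints
LEARNED_LIMBS: dict[str, tuple[str, str]] = {
    "l_upper_arm": ("l_shoulder", "l_elbow"),
    "r_upper_arm": ("r_shoulder", "r_elbow"),
    "l_forearm": ("l_elbow", "l_hand"),
    "r_forearm": ("r_elbow", "r_hand"),
}

PHASES = ("initialization", "learning", "fixation")


@dataclass
class LearnerConfig:
    """Parameters of the running-average limb learner.

    n_samples:
        ``N`` — accepted samples before the estimate is considered stable
        (default 200 frames, ~6.7 s of standing at 30 fps).
    max_dist:
        ``MaxDist`` (mm) — disparity between the learned and the instant
        length that triggers re-learning after fixation.
    min_confidence:
        Confidence both ending joints must reach for a frame to be accepted;
        1.0 discards tracker-estimated (0.5) centroids, whose positions are
        guesses and would bias lengths.
    reset_on_disparity:
        If True (default), a post-fixation disparity resets the counter to
        restart learning; if False, the sample is averaged in with the running
        coefficients instead (the guard-only behavior).
    noise_sigma:
        Optional per-coordinate centroid noise estimate (mm).  When set, the
        chi-distribution bias of noisy Euclidean distances is compensated by
        subtracting ``3 sigma^2 / (2 l̄)`` from each accepted sample.
    """

    n_samples: int = 200
    max_dist: float = 50.0
    min_confidence: float = 1.0
    reset_on_disparity: bool = True
    noise_sigma: float | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")


@dataclass
class LimbLengthState:
    """Running-average state for one limb."""

    limb: str
    estimate: float = 0.0  # l̄, mm (meaningful once k >= 1)
    k: int = 0
    resets: int = 0
    rejected: int = 0

    def phase(self, config: LearnerConfig) -> str:
        if self.k == 0:
            return "initialization"
        return "learning" if self.k < config.n_samples else "fixation"

    def to_dict(self) -> dict:
        return {"limb": self.limb, "estimate_mm": float(self.estimate), "k": self.k, "resets": self.resets}

    @classmethod
    def from_dict(cls, d: dict) -> "LimbLengthState":
        return cls(limb=d["limb"], estimate=float(d["estimate_mm"]), k=int(d["k"]), resets=int(d.get("resets", 0)))


def new_learner_states(limbs=LEARNED_LIMBS) -> dict[str, LimbLengthState]:
    return {limb: LimbLengthState(limb) for limb in limbs}


def instant_limb_length(frame, limb: str, min_confidence: float = 1.0) -> float | None:
    """Distance between a limb's ending raw centroids, or None if unreliable.

    Frames where either ending joint fails the confidence requirement are
    discarded (returns None).
    """
    if limb not in LEARNED_LIMBS:
        raise KeyError(f"unknown learnable limb {limb!r}")
    a, b = LEARNED_LIMBS[limb]
    if frame.confidence[a] < min_confidence or frame.confidence[b] < min_confidence:
        return None
    return float(np.linalg.norm(frame.positions[a] - frame.positions[b]))


def update_limb_length(state: LimbLengthState, l: float | None, config: LearnerConfig) -> LimbLengthState:
    """One running-average step; pure (returns a new state).

    During learning (k < N): ``k += 1``, ``l̄ += (l - l̄)/k`` (so the first
    sample sets the estimate exactly).  After fixation: no change while the
    disparity stays within ``MaxDist``; beyond it the limb is re-learned from
    scratch (counter reset) or, with ``reset_on_disparity=False``, averaged in
    with the running coefficients.
    """
    if l is None:
        return state
    if l <= 0:
        return replace(state, rejected=state.rejected + 1)
    if state.k < config.n_samples:
        k = state.k + 1
        return replace(state, k=k, estimate=state.estimate + (l - state.estimate) / k)
    if abs(state.estimate - l) > config.max_dist:
        if config.reset_on_disparity:
            return replace(state, k=1, estimate=l, resets=state.resets + 1)
        k = state.k + 1
        return replace(state, k=k, estimate=state.estimate + (l - state.estimate) / k)
    return state


def learner_step(
    states: dict[str, LimbLengthState],
    frame,
    config: LearnerConfig,
    model=None,
) -> dict[str, LimbLengthState]:
    """Update every limb from one raw frame; refresh model lengths in place.

    The learner consumes raw (pre-gating) centroids; limbs whose ending joints
    are unreliable in this frame are skipped individually.
    """
    out = {}
    for limb, state in states.items():
        l = instant_limb_length(frame, limb, min_confidence=config.min_confidence)
        if l is not None and config.noise_sigma is not None and state.estimate > 0:
            l = l - 3.0 * config.noise_sigma**2 / (2.0 * state.estimate)
        new = update_limb_length(state, l, config)
        out[limb] = new
        if model is not None and new.k >= 1:
            model.limb_lengths[limb] = new.estimate
    return out


def save_states(states: dict[str, LimbLengthState], path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({limb: s.to_dict() for limb, s in states.items()}, fh, sort_keys=False)


def load_states(path) -> dict[str, LimbLengthState]:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {limb: LimbLengthState.from_dict(d) for limb, d in data.items()}
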