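# kinfilter

Model-based kinematics reinforcement of noisy RGB-D skeleton-tracker streams.

Consumer depth sensors with OpenNI/NITE-style middleware deliver per-frame 3D
centroids of 8 upper-body parts (torso, head, shoulders, elbows, hands), each
with a confidence value in {0, 0.5, 1} — but no guarantee the implied pose is
humanly possible. Limb lengths fluctuate, elbows bend the wrong way, an
occluded hand inherits the depth of the body part hiding it, and an object in
the hand stretches the apparent arm. `kinfilter` wraps such a stream in an
articulated kinematic model that gates unreliable centroids, solves each arm
by analytic inverse kinematics under joint limits and self-collision
constraints, interpolates smooth validated trajectories, and learns the
performer's limb dimensions online. It is aimed at people building gesture,
rehabilitation or robotics applications on skeleton trackers who need poses
that are *valid by construction*, plus the machinery to evaluate such a filter
without sensor hardware.

## The model in brief

All positions are mm in a right-handed torso-rooted frame (+y up, +z toward
the camera, +x the performer's left). Segment lengths start from stature `H`
via the Drillis–Contini proportions (`H = H_e/0.936` from the floor-to-eye
distance; upper arm 0.186 H, forearm 0.146 H, …) and adapt online with a
running average with time-varying coefficients

    l̄(t_k) = l̄(t_{k-1}) + ( l(t_k) − l̄(t_{k-1}) ) / k,        k ≤ N

which equals the exact mean of the accepted instant lengths; after `N`
samples the estimate freezes unless the disparity exceeds `MaxDist`, which
restarts learning. Per frame, centroids with confidence < 0.5 are replaced —
hands from the previous observation, elbows from the model:

    ∀ i ∈ EE with c < 0.5 :  p_i(t_k) ← p_i(t_{k-1})
    ∀ i ∈ IJ with c < 0.5 :  p_i(t_k) ← p_i^m(t_{k-1})

Hand targets are clamped into the reach annulus `[|l_ua−l_fa|+ε, l_ua+l_fa]`,
elbow flexion follows from the law of cosines, and the redundant swivel angle
picks the valid elbow closest to the observed elbow centroid. Invalid poses
are replaced by the closest valid alternative (obstacle push-out toward the
previous hand position, then a reach × swivel search). A cubic interpolator
joins consecutive key poses with every substep re-validated; it introduces a
constant 2-sample delay (~66 ms at 30 fps) and can be switched to linear
(1 sample) or off. Self-collision uses a two-level test: axis-aligned
bounding boxes first, an exact capsule narrow phase only for overlapping
pairs.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import kinfilter as kf
from kinfilter import synthetic_tracker as st, pose_filter as pf

model = kf.build_default_model(stature_h=1750)          # mm
truth = st.generate_motion(model, duration=30, rate=30, seed=1)
frames = st.corrupt_stream(truth, st.CorruptionSpec(seed=2))

result = pf.filter_stream(frames, model)

def err(seq, getter, joint):
    return np.mean([np.linalg.norm(getter(seq[k], joint) - truth[k].joint_positions[joint])
                    for k in range(len(truth))])

for joint in ("r_hand", "r_elbow", "r_shoulder"):
    raw = err(frames, lambda f, j: f.positions[j], joint)
    filt = err(result.key_poses, lambda p, j: p.joint_positions[j], joint)
    print(f"{joint:10s}  raw {raw/10:5.2f} cm   filtered {filt/10:5.2f} cm")

fa = result.learner["r_forearm"]
print(f"learned forearm: {fa.estimate:.0f} mm after {fa.k} samples "
      f"(model prior was {0.146*1750:.0f} mm)")
print(f"output delay: {result.delay_samples} samples")
```

prints

```
r_hand      raw  3.27 cm   filtered  3.27 cm
r_elbow     raw 12.83 cm   filtered  8.48 cm
r_shoulder  raw  1.25 cm   filtered  0.00 cm
learned forearm: 292 mm after 94 samples (model prior was 255 mm)
output delay: 2 samples
```

Reading it: the hand is observed confidently and inside reach, so the filter
follows it and cannot remove its noise; the elbow is constrained to the
kinematically reachable circle, cutting its error by a third; the shoulder is
anchored to the model (the synthetic truth shares the model's geometry, hence
zero). The learner's forearm estimate sits above the prior — noisy Euclidean
distances overestimate lengths, and the heavy extension-dependent elbow noise
in this stream keeps the counter resetting — yet the adapted model still
beats both the raw tracker and a fixed-proportion model.

The same pipeline is scriptable from a shell:

```
kinfilter simulate --duration 10 --rate 30 --seed 1 --out stream.jsonl
kinfilter filter stream.jsonl --out poses.jsonl --bvh-out poses.bvh
kinfilter calibrate pointsA.csv pointsB.csv --mode rigid
kinfilter align trajA.csv trajB.csv --rate 60
```

Streams are JSONL (`{"t": .., "joints": {name: {x, y, z, c}}}`) or long-form
CSV (`t, joint, x, y, z, c`); poses export to JSONL or BVH.

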