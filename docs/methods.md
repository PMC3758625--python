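# Methods

## Problem and approach

Consumer depth-sensor skeleton trackers (OpenNI/NITE-style middleware over a
PrimeSense-class RGB-D camera) report, at ~30 Hz, one 3D centroid per body
part with a confidence value in {0, 0.5, 1}, but make no promise that the
implied pose is humanly possible: limb lengths fluctuate, elbows can bend
backwards, hands inherit the depth of whatever occludes them, and an object
held in the hand stretches the apparent arm. `kinfilter` reinforces such a
stream with an articulated upper-body model. Every emitted pose is produced
by forward kinematics of a model whose joint limits, segment lengths and
collision proxies are enforced — validity holds by construction, not by
post-hoc checking.

The pipeline per frame:

1. **Confidence gating.** Centroids with confidence < 0.5 are replaced: hands
   (end effectors) by their previous raw observation, elbows (intermediate
   joints) by the model's previous position. Confidence 0.5 means the tracker
   itself already estimated the centroid; those pass through. Shoulders, head
   and torso pass through untouched by default (a flag holds them from the
   model instead).
2. **Reachability clamping.** Each hand target is projected into the arm's
   reach annulus `[|l_ua − l_fa| + ε, l_ua + l_fa]` along the shoulder→target
   ray (ε = 1 mm keeps the elbow away from its singular, fully-folded
   configuration). A target beyond reach — the object-in-hand failure — thus
   yields a fully stretched, kinematically coherent arm aimed at the target.
3. **Analytic IK.** Elbow flexion follows from the law of cosines; the elbow
   lies on a circle around the shoulder–hand axis. The redundant swivel angle
   is chosen as the valid candidate whose elbow is closest to the observed
   elbow centroid (the elbow observation steers redundancy but can never
   leave the reachable circle), falling back to the previous pose's swivel.
   Candidates violating joint limits or colliding with the torso, head or the
   other arm are discarded; the sweep uses 64 uniformly spaced swivels.
4. **Pose repair.** If no candidate survives, the target is first pushed out
   of any penetrated collision proxy *toward the previous hand position* —
   this is what keeps an occluded hand behind the torso or head rather than
   snapping it to the camera-facing side — and re-solved; failing that, a
   reach × swivel sweep with per-DOF limit clamping returns the valid pose
   whose hand is closest to the desired target; the previous pose and the
   neutral pose are terminal fallbacks.
5. **Interpolation.** Consecutive key poses are joined by a cubic Hermite
   segment on the hand trajectories with finite-difference (central) slopes.
   Each substep (default 4 per frame pair) is re-solved through IK and
   validated, so a blend that would sweep one arm through the other is bent
   around the collision. Because the end slope of a segment needs one future
   key point, the emitted stream lags the input by exactly 2 samples (~66 ms
   at 30 fps); a linear interpolator (1 sample) or none (0) can be selected
   when latency matters. Error statistics are computed on the
   delay-compensated key-pose sequence, mirroring the cross-correlation
   alignment used for cross-system comparison.
6. **Re-acquisition slew limiting.** When a hand's confidence recovers after
   an occlusion, the target walks from the held position toward the new
   centroid at most `max_reacquire_step` (default 100 mm/frame), so the
   output never teleports. Normal tracking is unaffected (typical inter-frame
   hand motion is far below the cap), and the cap deliberately does not apply
   to confident-but-unreachable targets, where the immediate full-arm stretch
   is the intended behavior.

## Anthropometry and online limb learning

Segment lengths are initialized from stature `H` using the Drillis–Contini
body-segment proportions (upper arm 0.186 H, forearm 0.146 H, half biacromial
0.129 H; the shoulder line sits 0.235 H above the mid-torso root and the face
centroid 0.355 H). `H` itself comes from the floor-to-eye distance:
`H = H_e / 0.936`, with `H_e` the mean face-centroid height while the
performer stands still. These are shipped as an editable configuration table,
not constants.

Arm segment lengths then adapt online. The instant length of a limb is the
distance between its ending raw centroids, accepted only when both
confidences are 1 (tracker-estimated centroids would bias lengths). A
running average with time-varying coefficients,
`l̄_k = l̄_{k−1} + (l_k − l̄_{k−1})/k`, makes the estimate equal the exact
arithmetic mean of accepted samples during the first `N` frames. After `N`
samples the estimate freezes (*fixation*); if the disparity between the
estimate and an instant length exceeds `MaxDist`, the counter resets and the
limb is re-learned, restoring fast adaptation. A flag selects the alternative
guard-only behavior (keep averaging with the running coefficients instead of
resetting). Defaults `N = 200` frames (~6.7 s of standing at 30 fps) and
`MaxDist = 50 mm` were chosen so fixation follows one stable standing phase
while resets tolerate centroid noise at the magnitudes the corruption model
uses; both are configuration.

Euclidean distances of noisy endpoints overestimate the true length (the
noncentral-chi bias, ≈ 3σ²/(2l̄) for per-coordinate noise σ on the relative
position). With σ ≈ 21 mm relative noise on a 255 mm forearm this is ~2.6 mm
— small against `MaxDist`. An optional correction subtracts the bias when a
noise estimate is configured; it is off by default because σ is rarely known.

## Model geometry and collision detection

The model anchors the arms at fixed shoulder positions scaled from `H`;
tracker shoulder centroids feed limb learning but not the pose. This keeps
every emitted pose exactly FK-consistent (all segment-length invariants hold
to machine precision), at the cost of ignoring shoulder-girdle motion — an
accepted simplification of the upper-body model (the filter corrects arms;
shoulder errors are dominated by the model offset, which the synthetic truth
shares).

Each arm has 4 DOF: shoulder flexion (about x, −60°…180°, positive forward),
abduction (about z, ±: 90° away from the body, 45° across it), internal
rotation (±90° about the upper-arm axis), and elbow flexion (0…145°, no
hyperextension). The ranges follow standard clinical goniometry tables and
live in the configuration. The decomposition places overhead reach in
flexion, so abduction stays within ±90° and the gimbal configuration (arm
pointing straight sideways) is handled by folding residual rotation into the
internal-rotation DOF.

Collision detection is two-level: an axis-aligned bounding-box broad phase
(closed intervals — boundary contact counts, erring toward separation),
then an exact narrow phase only for pairs whose boxes overlap. Proxies are
capsules (head = sphere, torso = a thick vertical capsule of radius 0.065 H;
arm capsule radii are fractions of segment length: 0.14 upper arm, 0.12
forearm), so the narrow phase reduces to a closed-form segment–segment
distance against the radius sum. A tessellated mesh of each capsule is kept
for export and for auditing the conservative-AABB invariant; it is inscribed
in the analytic capsule. Adjacent segments (sharing a joint) are excluded
automatically from the pair list.

## Synthetic tracker emulator

No public recordings of this stream class exist, so the emulator defines the
test conditions. Ground-truth motion is a cubic spline through way-poses in
joint-angle space: random way-poses are rejection-sampled inside the limits
until valid; any sampled frame that lands invalid through spline overshoot is
repaired by re-solving its hand positions through the IK machinery. The
corruption stage then adds, per joint, i.i.d. Gaussian centroid noise at
magnitudes typical of depth trackers (hands 20 mm, elbows 30 mm, shoulders
8 mm, torso/head 5 mm per axis), with the elbow σ multiplied by
`1 + g·r` (g = 2), `r` the arm-extension ratio — reproducing the observation
that elbow oscillation grows as the arm stretches. Scheduled events emulate
the documented failure modes: occlusions (confidence 0 or 0.5; the reported
position freezes at the last reliable value plus a 5 mm/frame drift — how
the real tracker extrapolates occluded centroids is undocumented, so this is
an explicit stand-in), depth hijack (an occluded hand keeps confidence 1 but
its camera-axis coordinate is replaced by the occluder's), and object-in-hand
(the hand centroid slides along the forearm axis).

The torso-occlusion scenario moves the right hand along a cylindrical arc
around the body — front, past the right side, to behind the back — and
hijacks the hand's depth exactly while the hand is inside the torso's
silhouette as seen from the camera (camera at (0, 0, 1700) mm in the torso
frame, echoing a ~1.7 m capture distance). Hijacking only inside the
silhouette matters: a bogus depth on a hand that is visibly lateral is
kinematically plausible and no model-based filter could detect it.

Frames are scored by region categories: a joint is *behind* / *aligned with*
/ *in front of* a reference joint when the camera-distance difference exceeds
+Θ_d / lies within ±Θ_d / falls below −Θ_d (torso reference uses Θ_d =
100 mm; farther-from-camera = behind, with the sign configurable).

What passing these synthetic tests does **not** show: performance against
real depth hardware (sensor-specific noise is neither Gaussian nor
independent across joints), tracking of performers whose proportions drift
from the Drillis–Contini table in ways the learner cannot see (e.g. clothing
bulk), shoulder-girdle and torso articulation, or leg tracking. The synthetic
truth is generated by the same kinematic model the filter uses, so model-bias
errors (wrong proxy shapes, wrong ratios) are invisible by construction; the
cross-system calibration module exists precisely so real recordings can be
scored against an external reference.

## Cross-system calibration and alignment

The 4-point correspondence transform is provided in two modes: the literal
block solution `RT = B A⁻¹` of the homogeneous system (exact, but the 3×3
block is not constrained to be a rotation, so marker noise leaks into shear;
it requires non-coplanar points) and an orthogonal least-squares (Kabsch/SVD)
mode, the default for practical use. Trajectories are oversampled to a common
rate with cubic splines. The residual time offset is estimated per joint as
the argmax of the normalized (Pearson, per-axis averaged) cross-correlation
within ±2 s; among the hand/elbow/shoulder candidates, the lag maximizing the
mean correlation across all three joints is applied to all of them, ties
breaking toward smaller |lag|. Per-axis correlation (rather than correlating
distance-from-origin profiles) was chosen because it preserves directional
timing information and is amplitude-invariant. Flat trajectories are excluded
from the candidate set. Error summaries report per-frame Euclidean distances
with mean and population SD.

## Numerical choices and degenerate inputs

* Reach-annulus ε: 1 mm. Swivel grid: 64 (solve) / 32 (repair) samples;
  repair reach grid: 10 distances. Swivel ties break toward the smaller
  change from the previous pose, then the smaller grid index.
* A hand target coincident with the shoulder has no direction; the previous
  frame's hand direction (or the hanging-arm direction) substitutes.
* A straight arm makes internal rotation unobservable from positions; the
  previous pose's value is retained.
* Segment–segment distance uses the standard clamped closest-point
  computation with guards for degenerate (zero-length) segments, which is
  how the head sphere is handled.
* Pose invariants (limb-length conservation, FK reproducibility) hold to
  1e-6 relative; transform recovery and AABB conservativeness are exact to
  1e-9 on clean input.
* Problem sizes used by the shipped checks: 10–30 s streams at 30 Hz,
  20-seed batteries for the stochastic comparisons, 10⁴-frame fuzz for the
  validity guarantee, 100-seed battery for length recovery. These sizes give
  stable win-rates while keeping the full battery in the minutes range on a
  single core.

## Known limitations

* The shoulder girdle is rigid; clavicular elevation/protraction is not
  modeled, so reaches far across the body resolve with more elbow/swivel
  distortion than a human would use.
* The elbow is a pure flexion hinge (no measured carrying angle, pronation
  folded away since hands are points).
* The swivel-angle discretization is a deliberate parameterization of arm
  redundancy, not a reconstruction of any particular published analytic
  solver's internals.
* The repair search is optimal only over the candidates it evaluates; the
  returned "closest valid" hand is within the grid resolution of the true
  constrained optimum.
* Confidence semantics are trusted as given; a confidently wrong centroid
  (depth hijack) is only corrected when it is kinematically impossible or
  collides.
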