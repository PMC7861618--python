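# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `skilledreach` pipeline and its synthetic-data
generator.

## Mirror-stereo geometry

A planar mirror gives a single camera a second viewpoint: the mirror image
of a world point X equals the direct image of X reflected across the
mirror plane (n&middot;X = d, n unit length). The equivalent "virtual"
camera behind the mirror is the reflection of the real camera — an
improper rigid transform, so the virtual camera is left-handed and cannot
be used directly in standard two-view machinery, which assumes proper
rotations (det R = +1).

**Handedness flip.** Before any two-view computation, the mirror view's
horizontal pixel coordinate is reflected about the principal-point column,
u &rarr; 2c_x &minus; u. This particular flip (rather than a raw sign
negation) was chosen because it conjugates the intrinsic matrix onto
itself: the flipped mirror view is a proper pinhole camera with the *same*
K as the direct view, so E = K&#7488;FK holds with a single intrinsics
matrix. The flip is a pixel-space isometry, so reprojection errors
measured in flipped coordinates equal those in raw coordinates. With the
camera at the world origin the flipped mirror camera's ground-truth
extrinsics are [R|t] = D[H|h], D = diag(&minus;1, 1, 1), where [H|h] is
the mirror reflection; the calibration tests verify recovery of exactly
this pose.

**Calibration.** F is estimated by the Hartley-normalized eight-point
algorithm over all corner pairs (no RANSAC by default — calibration
corners are curated; degenerate configurations are rejected when the
design matrix's ratio of largest to eighth singular value exceeds 1e12).
Rank 2 is enforced by zeroing the smallest singular value. E = K&#7488;FK
is projected onto the essential manifold (two equal singular values, one
zero), decomposed into four (R, t) candidates, and the candidate placing
&ge; 75% of calibration points in front of both cameras is selected
(cheirality; the margin tolerates a few noise-corrupted corners).
Intrinsics are supplied via configuration, not estimated: the rig's K is
known and the checkerboard cube is too shallow a target for reliable
self-calibration.

**Metric scale.** Reconstruction with |t| = 1 is metric up to one global
factor, fixed so the *first listed* adjacent-corner pair spans the known
checkerboard square (4 mm). The remaining ~70 adjacent pairs serve as a
consistency check (tested to 1e-6 mm at zero noise). With noiseless
corners the recovered scale equals the true camera-to-virtual-camera
baseline (240 mm for the default synthetic rig). Calibration corners are
treated as noise-free by default: corner localization on a physical
checkerboard is sub-pixel and averaged over images, whereas anchoring the
scale on a single 4 mm edge would amplify per-corner noise by the
edge-to-scene ratio. Tracking-label noise, the dominant error source, is
modeled separately.

**Triangulation.** Linear DLT per point, solved as a batched 3x3 normal
system (exact on noise-free input, and fast enough for millions of
points). Reprojection error is the mean over the two views of the
observed-vs-reprojected pixel distance. No nonlinear refinement is
applied; at the rig's ~50&deg; stereo angle the linear solution is within
a few percent of optimal and the 0.5 px label noise budget dominates.

## Reconstruction conventions and filtering

* Confidence threshold 0.9 (both views) for triangulation.
* Reprojection threshold 3 px: swapped digit identities displace a label
  by the projected digit spread (tens of px), producing errors far above
  this; genuine labels at 0.5 px noise stay far below it.
* Gap bridging: a part missing in one view for &le; 5 frames (bounded by
  triangulated frames) is interpolated in 3D over time with pchip and
  accepted only if it projects within 3 px of the single remaining view's
  label; frames unlabeled in both views stay missing.
* Pellet frame: origin is the per-coordinate median pellet position over
  the 100 pre-trigger frames (median for robustness to sporadic
  mislabels; the estimator is configurable). Axes come from the chamber
  geometry (floor normal = y pointing down, reach direction = z), not
  estimated from data. Left-paw x negation happens here, once.

## Synthetic experiment generator

The generator defines the study conditions under which everything is
tested. The defaults are fixed, not tuning knobs.

* **Rig:** 2400 x 1024 px, f = 1700 px, principal point at the image
  center; mirror plane n &prop; (1, 0, 0.3), d = 120 mm; pellet 250 mm
  from the lens. This yields a ~50&deg; stereo angle and, at 0.5 px label
  noise, ~0.16 mm 3D RMSE — the regime a real mirror rig operates in.
* **Trials:** 1300 frames at 300 frames/s (300 pre-trigger, 1000 post);
  the reach begins within a few frames of the trigger, since the trigger
  *is* the paw crossing the slot. During-reach laser epochs span the beam
  break until 3 s post-trigger; between-reach epochs start 4 s
  post-trigger (outside the saved video).
* **Reach model:** the advancement coordinate follows a minimum-jerk
  advance from z = &minus;21 mm to an endpoint ~ N(3, 2) mm, then a
  minimum-jerk retraction; peak speed 850 mm/s sets the advance duration
  (~16 frames for a 24 mm reach, matching fast rodent reaches). Digit tips
  sit on a line through the digit-cluster center whose length is the
  aperture and whose frontal-plane angle is the orientation; both follow
  logistic profiles of z (aperture 5 &rarr; 14 mm, half-point &minus;7 mm;
  orientation 85&deg; &rarr; 30&deg;, half-point &minus;8 mm) — digits
  spread and the paw pronates as it approaches the pellet. The pellet is
  held stationary for the whole trial (post-contact pellet motion is out
  of scope).
* **Outcomes** emerge from a grasp rule: first-reach success iff max
  extent lands in [0, 6] mm with aperture &ge; 3 mm (one pellet diameter)
  at z = 0; shorter reaches leave the pellet (code 7), longer or
  too-closed reaches knock it off (code 4); 15% of failed first reaches
  get a second attempt which can convert to code 2. Small probabilities of
  no-pellet (2%), trigger-error (3%) and paw-through-slot (1%) trials
  exercise the denominators and flags. The grasp window and pellet
  diameter are configurable placeholders — outcome scoring in real data is
  human — chosen so success collapses mechanistically when extent drifts.
* **Effect schedules:** during-reach stimulation accumulates per-session
  drift on laser sessions (extent &minus;1.5 mm, aperture and orientation
  half-points &minus;0.8 mm, peak speed &minus;40 mm/s per session; small
  within-session drift of &minus;0.01 mm/trial), reverting fully on the
  first occlusion session (recovery rate 1.0, matching rapid recovery;
  configurable). During-reach inhibition shifts only the aperture
  half-point, in the opposite direction. Between-reach and control groups
  get the laser condition without kinematic change. Abrupt mode alternates
  the laser every 5 trials (starting off) with a state-dependent shift
  (extent &minus;3 mm, aperture half-point &minus;1.5 mm) and no drift —
  kinematics follow the laser trial-by-trial.
* **Degradation:** Gaussian label noise (0.5 px), missing detections
  (2% per label, confidence drawn below threshold), digit-identity swaps
  in a single view and frame (0.2% per frame-view) — the specific failure
  mode reprojection filtering must catch. Out-of-image projections are
  marked missing.
* **Scale:** 6 rats per group, 60 trials per session, sessions = 2
  retraining + 10 laser + 10 occlusion. The two retraining sessions are
  exactly the ones entering the analysis baseline; earlier training
  sessions carry no information the analysis uses, so they are not
  simulated. At experiment scale the generator stores per-trial summaries
  plus deterministic re-render recipes (per-trial seeds) instead of full
  frame arrays; a test verifies stored summaries match the full
  render-and-reconstruct path.

What the generator does *not* emulate: tracking-confidence correlations
with pose, lens distortion, pellet displacement after contact,
multi-reach grasp corrections beyond a single second attempt, tongue use,
and human scoring noise in outcome codes. Passing tests therefore
demonstrate the pipeline's correctness and sensitivity under idealized
tracking statistics, not robustness to every real-world tracking
pathology.

## Reach segmentation

Start: from the first frame with z_digit2 outside the slot plane
(&minus;15 mm), walk backwards while the paw dorsum's per-frame &Delta;z
is positive; the start is the frame after the last non-positive step (a
zero threshold avoids a free parameter). End: the frame holding the
maximum z_digit2 before *sustained* retraction, defined as a cumulative
drop &ge; 0.5 mm below the running maximum; for an exact plateau the last
plateau frame is taken. On clean data this is exactly "the frame at which
the digit tip begins to retract"; the hysteresis exists because at 0.5 px
label noise (~0.1 mm in z) a literal first-decrease rule fires a few
frames early near the velocity zero-crossing. A subsequent reach requires
full retraction below the slot plane first (the reset depth is the one
genuinely open segmentation choice; full retraction is assumed). Jitter
rejection: a reach must advance &ge; 2 mm beyond the slot and last &ge; 3
frames. Trials beginning with the paw already outside are flagged
`paw_through_slot` and excluded from rate denominators.

## Coordination profiles

Within a reach, the retained frames are the strictly-increasing running
maximum of z_digit2 (z-parameterized interpolation needs a single-valued
function; this rule drops retraction jitter without inventing data). Each
digit-tip coordinate is interpolated as a pchip function of z_digit2 and
evaluated on the fixed grid &minus;20.0(0.1)15.0 mm; pchip is
shape-preserving, so no overshoot beyond the data range on monotone
segments (tested). Grid points outside a reach's observed range are
masked, and shorter reaches are excluded from averages at coordinates they
never attained. Orientation uses the frontal-plane (x–y) projection of the
digit1&ndash;digit4 segment, angle in [0&deg;, 90&deg;]; the
segment-to-plane 3D angle is an equally valid reading of "angle with the
floor" and could be added behind a flag, but the frontal projection
matches the head-on view in which the measure is defined.

## Statistics

Mixed models are fit by REML (statsmodels MixedLM) with rat as the
grouping factor; the random structure (intercept-only, laser slope,
session slope) is specified per analysis. Inference uses t statistics on
residual degrees of freedom (observations minus fixed-effect rank); a
Satterthwaite approximation is not available in the backend, and at the
session-level sample sizes here (&ge; 128 residual df) the two are
practically indistinguishable. Near-singular random-effects fits are
flagged but still return fixed effects; the optimizer falls back from
L-BFGS to Powell to ML if the Hessian is indefinite. Normalized rate and
count responses are asinh-transformed before fitting (asinh(0) = 0 handles
zero-success sessions). Trialwise group comparisons use the Wilcoxon
rank-sum per trial at a raw p &lt; 0.01 cutoff with no multiplicity
correction — deliberately, as a descriptive within-session trace; its
per-trial type-I error is verified to sit near the nominal level (exact
small-sample p-values, doubled-tail convention). Kruskal–Wallis, paired t
per extent bin, and the exact binomial sign test (ties dropped; all-ties
undefined) complete the battery.

## Problem sizes and determinism

Test and acceptance runs use: 500 noisy trials for segmentation accuracy,
200 reaches per condition for coordination recovery, 20 replicates of the
full 3-group experiment for gradual-effect recovery, 20 replicates of 6
rats x 2 alternating sessions for abrupt-effect recovery, 1000 replicates
for rank-sum calibration and 200 for mixed-model CI coverage. These sizes
give binomial standard errors comfortably inside the asserted margins.
All randomness flows through `numpy.random.Generator` seeded explicitly;
identical seeds and configuration reproduce experiments, renders, and
pipeline outputs byte-for-byte.

## Known limitations

* One mirror view per reconstruction; the second (nose-side) mirror of a
  physical rig is not fused.
* No lens-distortion model and no bundle adjustment; K is trusted as
  given.
* Outcome codes for real data must come from human scoring; the
  mechanistic grasp rule applies only to synthetic ground truth.
* The pellet is assumed trackable pre-reach; trials without a tracked
  pellet cannot be placed in the pellet frame and are dropped from
  kinematic (not outcome) analyses.
* Degrees of freedom are residual-based, slightly anticonservative for
  small numbers of rats with random slopes.
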