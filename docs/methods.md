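# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is assumed, what is
tunable, and what the synthetic tests do and do not demonstrate.

## Forward model of a hop

The cloaca is treated as a point mass in free flight over flat ground:
`c(t) = c0 + v0 t − ½ g t² e_z` with `g = 981 cm s⁻²` (the package works
in cm throughout). Flight ends when the cloaca returns to take-off height;
before launch and after landing the animal sits still, so every simulated
trajectory contains ground frames on both sides of the hop (12 frames of
padding by default), which is what the take-off/landing detector expects.
Drag, non-planar ground and multi-hop bounding are out of scope.

The snout sits `body_length_axis` cm from the cloaca (the snout–vent
length, so SVL in mm / 10) along an axis whose elevation interpolates
linearly in time between the planted take-off and landing body angles.
Within-flight posture is not otherwise modelled; linear interpolation is
the simplest choice that leaves the two planted angles exactly recoverable
at the bracket frames. The elevation of the take-off *velocity* vector and
the take-off *body-axis* angle are deliberately independent parameters:
published "take-off angle" could denote either reading, and keeping both
planted makes either testable.

Closed forms used as oracles: range `v² sin 2θ / g`, apex
`v² sin² θ / (2g)`, flight time `2 v sin θ / g`.

## Synthetic stereo rig

Two pinhole cameras mirror the field protocol: 10 cm tripod height, 20 cm
baseline, 240 fps, an angle of 140° between the optical axes (each camera
yawed inward by (180° − 140°)/2 = 20°), placed 150 cm from the arena
midline. The sensor is a 4K-class format (4096 × 2160, focal length 1800
px): with the 20 cm baseline at ~1.5–2 m range this yields ~0.4 cm RMS
triangulation error under the default 0.5 px isotropic Gaussian landmark
noise, and sub-micrometre error without noise. Lens distortion is not
modelled, and no images are rendered — "observations" are projected pixel
coordinates plus noise, with points behind a camera or outside the sensor
flagged invisible rather than dropped.

Synchronization uses a single planted flash spike per brightness trace;
the estimated offset is the difference of the trace argmaxes, guarded by a
prominence threshold (default 50 brightness units above the median).

## Calibration and QC

Cameras are estimated by Hartley-normalized DLT resectioning on
checkerboard corner correspondences pooled across board poses (several
poses of a planar board give a non-coplanar 3D point set; a single pose is
rejected as degenerate). This replaces the planar-toolbox optimization
used with the original recordings: the observable contract — a calibrated
stereo pair with per-view quality control — is the same, and the linear
estimator is exactly testable (noiseless resection reprojects to ≤1e-8
px).

The 1% accuracy rule is operationalized as: triangulate all corners of a
view, rigidly fit the known board model to the reconstruction (Kabsch),
and divide the RMS corner discrepancy by the board width; views above
threshold 0.01 are suppressed. Because a grossly corrupted view also
perturbs the cameras estimated from the pooled correspondences,
calibration iterates: estimate, score, drop the single worst failing view,
re-estimate, until all remaining views pass. Epipolar-distance metrics
would be an alternative operationalization; only the rigid-fit metric is
implemented.

Reconstruction triangulates snout and cloaca per frame after applying the
sync offset; interior gaps of at most 2 frames are linearly interpolated
and flagged, longer gaps or less than 90% two-view coverage reject the
trajectory. Triangulations with viewing-ray angles below 0.05° (e.g.
coincident cameras) are refused.

## Alignment and kinematic variables

Alignment is rigid (rotation + translation): the known vertical maps to
+z, the travel direction — the principal axis of the horizontally centred
cloaca path, signed by the net displacement — maps to +x, and the lateral
origin is placed on the fitted jump plane, making the squared lateral
coordinates least-squares minimal (for planar paths the take-off cloaca
lands exactly at the origin). A vertical hop has no defined heading and is
rejected.

Take-off is the last frame before the cloaca exceeds baseline + ε and
stays above for ≥3 frames; landing is the first frame after the apex back
within ε of baseline; ε defaults to 0.1 cm. Distance is the x displacement
of the cloaca between those frames; height the maximum cloaca rise above
the take-off baseline; velocities come from central differences of the
cloaca path (an optional 5-frame moving average is off by default); the
two angles are the signed elevations of the cloaca→snout vector at the
bracket frames. The cloaca (the ground-contact end of the body axis) is
the reference landmark for distance/height/velocity; using the snout or
the per-frame maximum would be a one-line change but is not exposed.
Frame quantization bounds the distance error by one inter-frame
displacement, v/fps (~1.4 cm at the fastest observed hops); mean velocity
covers flight frames only. Per animal, the longest hop is analysed; exact
ties go to the earliest trial id.

## Cohort generator

Each of the ten published generation × invasion-category × sex/age
cohorts is embedded as a preset (sample size n, per-trait mean and
standard error). Individuals are drawn with per-trait standard deviation
`se·√n`, so a cohort of the published size recovers the published mean
within its standard error. Linear measures are drawn conditionally on SVL
with correlation 0.7 (marginal spreads preserved) — a typical allometric
coupling, configurable. Morphology and jump performance are independent
by default, because the morphology→performance correlations are the
analysis target, not an assumption; an optional coupling plants them for
regression tests.

Jump distance and height (plus the two body angles) are planted per
individual and converted to launch parameters via θ = atan(4h/d),
v = √(d·g / sin 2θ). Velocities are therefore emergent, not planted: under
a ballistic model the published mean/maximum velocities are determined by
distance and height and cannot be matched independently. Draws are lightly
truncated to keep the forward model valid (distance ≥ 5 cm, height ≥ 0.5
cm, |body angles| ≤ 89°); juvenile SVL is truncated below the 90 mm sexing
cutoff, which biases the juvenile SVL mean down by well under one standard
error. The preset table carries no tibiofibula row, so that trait is
synthesized from the femur row (the two segments are nearly equal in
bufonids); treat tibiofibula analyses on synthetic cohorts as structural,
not calibrated.

Raceway trials simulate pokes at fixed intervals: refusal with probability
p (no displacement), otherwise a truncated-normal hop, until the 15 m wall
or 10 consecutive refusals. Summaries report per-5 m segment times and hop
counts (partial final segments flagged, not dropped), mean hop distance
(final position / hops) and speed over the distance actually covered —
the completed-distance convention for non-finishers.

## Statistical layer

The nested ANOVA treats population as a *fixed* factor nested within
invasion category, tested against the residual mean square — matching the
large denominator degrees of freedom in the published tables; a
random-effects variant is out of scope. Sums of squares are Type III
(partial, sum-to-zero coding), the convention of the JMP software used for
the original analyses. When every category holds exactly one population
the model collapses to a one-way ANOVA; a mix of single- and
multi-population categories is a nesting-degeneracy error. A constant
response returns F = 0 for all terms.

The "traits as repeated measure" MANOVA is implemented as profile
analysis: successive differences of adjacent trait columns form
within-subject contrasts, and a one-way MANOVA of those contrasts on
invasion category tests the category × trait interaction. Wilks' Λ with
Rao's F approximation (exact for two categories) is the default; Pillai's
trace is available. The reported numerator df follows the
(traits − 1) × (categories − 1) convention.

Backward elimination refits the full OLS model and removes the term with
the largest p ≥ 0.05 (ties to the later column), recording the removal
trace; predictors correlated beyond |r| > 1 − 1e-10 raise a collinearity
error naming the pair. Pearson correlations use the standard two-sided
t-test. Monte-Carlo tests confirm that all four procedures hold their
nominal 5% type-I error within ±0.02 under their nulls and that a 2-sd
predictor is retained in ≥95% of replicates at n = 200.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline is internally consistent:
planted physics, geometry, and distributional structure are recovered at
the published scales, and the inferential procedures are calibrated. They
do not validate the ballistic model against real toads (real hops have
drag, compliant substrates, digitization error structure beyond isotropic
Gaussian noise, and non-linear posture changes), and the published field
F-ratios and correlations are not reproducible from synthetic data — the
generator plants cohort means, not the full covariance of the field data.
Problem sizes in the test suite (cohorts at their published n, 200–1000
Monte-Carlo replicates, 12 calibration views) were chosen as the smallest
sizes at which the checked statistics are stable.

## Known limitations

- No lens distortion, rolling shutter, or bundle adjustment; calibration
  quality is limited by the linear DLT estimator.
- The raceway generator's coupling between jump distance and hop distance
  is a convenience for smoke tests, not a behavioural model; reluctance to
  run is not modelled.
- Residual shape scores default to per-generation regressions (F0 and F1
  analysed separately); the original pooling level is not stated, and
  pooled/per-class fits are exposed as options.
- Mass is excluded from the residual-shape trait set by default (only
  linear measures are size-corrected in the published tables).
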