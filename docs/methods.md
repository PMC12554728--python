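# Methods

`kneests` quantifies how much the estimated knee biomechanics of a
sit-to-stand (STS) movement depend on the motion-analysis protocol. Four
protocol configurations are applied to the *same* marker and force-plate
data: two marker sets — an anatomical-landmark set ("IOR", 26 static / 20
dynamic markers, skin-mounted on bony landmarks) and a cluster-based set
("CAST", 36 / 28, rigid four-marker plates on the lateral mid-thigh and
mid-shank with anatomical landmarks calibrated into the plate frames) —
crossed with two joint models: chain inverse kinematics (IK, three
rotational degrees of freedom per joint, joint centres shared between
adjacent segments) and unconstrained per-segment 6DoF fits. Outputs are
compared with mean absolute variability (MAV), pairwise mean absolute
differences (MAD) against a 5° clinical threshold, paired Cohen's *d*,
and one-dimensional statistical parametric mapping (SPM).

Because patient recordings for this kind of study are generally not
redistributable, the package is built around a synthetic STS generator
with complete ground truth; every downstream stage is validated against
that truth.

## Coordinate conventions

Lab frame: right-handed, X anterior (subject facing +X), Y to the
subject's left, Z vertical. Segment frames: X mediolateral pointing to
the subject's *right* (the flexion axis), Y anterior, Z longitudinal;
all frames reduce to the identity orientation in an ideal T-pose. Joint
angles use the Cardan X–Y–Z sequence (`R = Rx·Ry·Rz`): flexion/extension
about X, ab/adduction about Y, internal/external rotation about Z. Left
side Y/Z angles are negated so adduction and internal rotation are
positive on both sides; knee flexion is the negative X angle (the shank
rotates posteriorly about the common rightward axis), hip flexion the
positive one. Frames are 0-based throughout.

Joint angles are **calibration-referenced**: the static T-pose defines
the zero of every joint. Concretely, the reported rotation is
`R̃(t) = (R_prox(t)ᵀ R_dist(t)) · (R0_proxᵀ R0_dist)⁻¹`, which is the
identity in the static trial regardless of marker-placement idiosyncrasy.
Knee moments are reported as net *external* moments (the negative of the
internal joint moment), resolved in the proximal (thigh) segment frame by
default (configurable: lab or distal), normalized by body mass (N·m/kg),
with component signs matched to the angle conventions so a flexing
external load is positive alongside a flexing angle.

## Synthetic data generator

**Anthropometry.** Stature ~ N(1680, 70) mm and BMI ~ N(28.9, 3.8) kg/m²
(truncated at ±2.5 SD) emulate an elderly knee-osteoarthritis cohort;
body mass follows from BMI. Segment lengths and marker layout scale with
stature using standard body-proportion coefficients. Anatomical markers
receive independent N(0, 3 mm) placement jitter per subject; cluster
plates are jittered rigidly (common translation + small rotation), so
their four markers stay exactly coplanar within the 131 × 80 mm plate.

**Operational ground truth.** The subject's "true" frames and joint
centres are *defined* as what the calibration conventions produce from
the noise-free, jittered T-pose markers (Bell-regression hip centre from
the pelvis landmarks; knee/ankle centres as epicondyle/malleolus
midpoints; the frame-construction rules below). Noise-free calibration
therefore recovers the truth exactly, which turns "model building is
correct" into a machine-precision test rather than a tolerance judgement.

**Motion.** The movement is sagittal: three generalized angles — pelvis
pitch, knee flexion, and shank pitch — follow per-subject quintic
(minimum-jerk) keyframe profiles: quiet sitting, a small backward sway,
forward trunk lean, rise, a 2 s standing hold, descent, and settling.
Defaults: 43 cm seat, 90.0° initial knee flexion (exact, by driving the
joints in the calibrated frames), three repetitions, markers at 100 Hz
and plates at 1000 Hz. Per-subject movement style (lean amplitude,
standing knee angle, phase durations) is sampled once per subject.
Transitions deliberately overlap so the hip angular velocity crosses
zero transversally at movement onset and termination — a tangential
(zero-slope) crossing would make those events ill-posed under noise.
Hip and knee joint rotations are pure flexion in the calibrated frames;
the pelvis position closes the chain so the right ankle stays planted
(the left wanders by the millimetre-scale jitter asymmetry). Feet remain
flat on their plates.

**Plate signals.** The total external wrench required by the generated
kinematics is computed segment by segment (Dempster masses, COM
fractions and radii of gyration; head+arms+trunk lumped with the pelvis;
derivatives by central differences at the marker rate) and split between
the plates and the seat with a smooth seat-unloading profile. The feet
COP and free vertical moment close the moment balance whenever the feet
carry the load; while seated, the seat wrench does. The seated baseline
foot load defaults to 5 N per foot — deliberately below the 10 N event
threshold so the literal seat-off rule is well defined — with
`realistic_seated_load()` providing a shank+foot-weight alternative for
sensitivity studies. By construction, inverse dynamics applied to the
true kinematics with these signals closes the whole-body balance to
numerical-differentiation precision (tested to <1e-6 N, <1e-3 N·m).

**Soft-tissue artifact (STA).** Each skin marker is displaced in its
segment frame by low-pass-filtered Gaussian noise (bandwidth 2 Hz)
scaled by a group amplitude (thigh/shank skin 10 mm, pelvis 5 mm, foot
3 mm) and *modulated by a motion-intensity envelope* (smoothed summed
joint speeds, floor 0.15): soft tissue wobbles with movement, and a
quietly seated subject shows almost none. Without this modulation the
hip-velocity onset rule drowns in artifact crossings that real
quiet-sitting data do not exhibit. Thigh skin markers additionally carry
a knee-flexion-coupled displacement (15 mm at 90° flexion) along a fixed
per-subject, anterior-dominant direction — the systematic, non-averaging
component that differentiates skin from cluster tracking. Cluster plates
move rigidly with smaller amplitude (3 mm translation, matched rotational
wobble), preserving plate rigidity. Measurement noise is white, 0.3 mm.
All artifact fields are generated at unit amplitude and then scaled, so
amplitude sweeps at a fixed seed rescale the *same* realization —
`ArtifactConfig.scaled_skin()` scales the thigh-skin terms only, the
lever used by the artifact-sensitivity analysis. Cohorts draw a
log-normal per-subject STA scale (σ = 0.25) so protocol sensitivity
varies across subjects.

**Ground-truth events** are obtained by applying the literal detection
rules to the noise-free truth signals (exact hip flexion, plate force
sum, hip-centre height) with an independent, brute-force implementation
— not by calling the detection module — so event-recovery tests compare
two genuinely different code paths.

## Model calibration

Static calibration averages marker positions over gap-free frames.
Frames: pelvis — origin mid-ASIS, X through the ASIS pair, anterior
direction via mid-PSIS; thigh — origin at the hip centre, Z toward it
from the knee centre, frontal plane via the epicondyles; shank —
likewise via the malleoli; foot — origin at the calcaneus, long axis to
the 2nd metatarsal head, sole plane via the 1st/5th heads. The hip
centre uses the Bell regression (0.36/0.19/0.30 of the inter-ASIS
distance, lateral/posterior/distal; configurable). Inertia comes from
the Dempster table shipped as YAML (thigh 0.100, shank 0.0465, foot
0.0145 of body mass). Every dynamic tracking target is stored as a
constant local vector in its segment's *anatomical* frame, so one rigid
fit per segment per frame reconstructs the anatomical frame directly;
CAST cluster calibration is the same mechanism (and an explicit
`calibrate_cluster` utility exposes the classic technical-frame
formulation). The exact identity of the dynamic subsets is not usually
published alongside the counts, so it is configuration, not code: IOR
drops the medial epicondyles, medial malleoli and 1st metatarsal heads
(26→20); CAST drops all epicondyles and malleoli (36→28).

The IOR thigh retains only two physical dynamic markers (greater
trochanter, lateral epicondyle); its 6DoF pose is made determinate by
adding the pelvis-reconstructed hip centre as a third, equally weighted
target — a documented approximation (negligible hip translation) that
any under-determined segment can reuse.

## Pose estimation

**6DoF**: weighted least-squares rigid transform per segment per frame
(SVD/Kabsch, proper rotation enforced; frames with <3 usable targets are
flagged invalid). **IK**: per frame, a damped Gauss–Newton
(Levenberg–Marquardt) minimization of all marker residuals over 24
generalized coordinates (pelvis pose + 3 Cardan angles at each hip,
knee, ankle), with an analytic chain Jacobian, equal marker weights,
warm start from the previous frame, and monotone cost by step rejection.
Convergence: gradient norm <1e-10 or step <1e-12 or relative cost change
<1e-12, max 200 iterations; a frame that hits the cap while the cost is
still creeping (<1e-4 relative per step) keeps its pose but stays
flagged in diagnostics. The Cardan parameterization is guarded at
|θy| ≥ 89°.

## Inverse dynamics

Bottom-up Newton–Euler per side: foot → shank → thigh, using COM
accelerations, angular velocities (skew part of Ṙ Rᵀ) and accelerations
from the pose series, per-foot plate wrench (50 Hz-filtered, decimated
to the marker rate), gravity and the full inertia dyadic. Where a plate
is nearly unloaded (|Fz| < 10 N) its COP is undefined; its moment
contribution is zeroed and flagged. Hip loads are computed as chain
intermediates only.

## Segmentation and normalization

Five events, each the first frame satisfying its rule after the previous
event: onset (hip angular velocity crosses zero into sustained flexion),
seat-off (summed vertical GRF surpasses 10 N), standing (hip centre
holds its maximum height within ±3 cm; plateau bounds give stand
start/end), seat-on (GRF back below 10 N), end (next hip-velocity zero
crossing). Two robustness details: the GRF threshold is applied to the
baseline-subtracted signal by default (feet resting on plates while
seated make the literal rule ambiguous; a `"literal"` mode retains the
raw reading), and the onset crossing must be followed by actual
sustained trunk flexion (velocity above 15°/s within its positive run) —
on clean signals this reduces exactly to the literal first crossing, and
a 0.25 s guard band keeps filter edge transients out of the search. Hip
velocity uses the 6 Hz-filtered flexion angle. Segmentation is
per-protocol by default (each protocol's own kinematics drive the
rules), with a shared-segmentation mode to isolate modelling effects
from event-timing effects.

Curves are cropped to [onset, end] and linearly resampled onto 101 nodes
(0–100% of the cycle, the SPM-community standard); the three repetitions
are averaged node-wise (mean and sample SD).

## Variability statistics

Computed per subject on repetition-mean curves, then averaged across
subjects (a pooled alternative would weight subjects by cycle length;
the per-subject order matches the paired design). MAV = mean over nodes
of the four-protocol range; MAD = mean over nodes of |a−b| per pair
(absolute, so subject-specific differences of opposite sign cannot
cancel); MAV ≥ every pairwise MAD holds node-wise by construction.
Kinematic MADs strictly above 5° are flagged clinically meaningful (the
strict inequality matches the reporting convention of flagging 5.02 but
not 5.00). Cohen's *d* is paired, from per-subject node-averaged curve
values per protocol, `d = mean(diff)/SD(diff)`, with the
normal-approximation CI `d ± 1.96·√(1/n + d²/2n)`; the exact scalar
reduction is configurable since conventions differ.

## SPM

Node-wise paired t statistics; field smoothness (FWHM, nodes) from the
gradient-based estimator `FWHM = √(4 ln 2) / RMS(normalized residual
gradients)`; the critical threshold t\* solves `E[EC] = α` for the
thresholded 1-D t field using the 0- and 1-dimensional Euler
characteristic densities with resel count `(n_nodes − 1)/FWHM`, split
across tails (two-tailed is the default; the direction of protocol
differences is not known a priori). Zero-variance nodes get a signed
infinite t, are excluded from smoothness estimation, and count as
trivially supra-threshold. A max-|t| sign-flip permutation threshold is
the independent cross-check (agreement within 5% on smooth Gaussian
nulls) and an alternative method. No correction is applied across the
protocol pairs and variables; the report notes this explicitly.
Type-I calibration under a smooth Gaussian null (n = 24, FWHM 10,
1000 replicates) lands inside the 95% binomial band around α = 0.05;
`scripts/acceptance.py` recomputes exactly this.

## Problem sizes and numerical choices

Cohort-level tests run 2–3 subjects × 3 repetitions through all four
protocols (the statistics layer is additionally exercised at n = 24 with
synthetic curves, where it is cheap); the event-recovery check uses 100
trials across 25 subjects; the artifact sweep uses thigh-skin scales
(1×, 2×, 3×) at identical seeds. Chosen once as representative working
sizes for the synthetic study; the full 24-subject default reproduces
the published design counts and runs in minutes. All randomness flows
through explicit integer seeds via `numpy` `SeedSequence`; identical
seeds give bit-identical outputs.

## What passing tests do and do not show

The generator's motion is sagittal and bilaterally symmetric, its STA is
band-limited Gaussian plus a flexion-locked drift, arm support is not
modelled (the seat absorbs the corresponding load), and event timing is
built to be detectable. Passing tests therefore demonstrate that the
*pipeline* is internally correct — calibration recovers known geometry,
both solvers agree with truth in the noise-free limit, inverse dynamics
closes the whole-body balance, events are recovered under realistic
noise, and the statistics are calibrated — not that any particular
published effect size on real patients is reproduced. Real recordings
add frontal/transverse-plane motion, muscle-activation-dependent STA,
marker occlusions and arm-support forces that this generator only
partially emulates, which is also why the package makes no numeric claim
about patient data.

## Known limitations

- No helical-axis or quaternion angle options; Cardan X–Y–Z only.
- No muscle forces, joint power, or hip/ankle headline outputs.
- C3D I/O is not provided; trials interchange via the documented TSV +
  JSON sidecar dialect.
- The IK solver assumes one connected lower-body chain with both feet
  instrumented; partial marker sets degrade to flagged frames rather
  than partial solutions.
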