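# Methods

`quailkin` re-implements, as a tested pipeline, the analysis chain used to
study how common quail (*Coturnix coturnix*) negotiate visible vertical
steps: markerless landmark localization, biplanar 3D reconstruction,
anatomical coordinate frames with Cardan angles, effective-leg variables,
stride normalization, and the statistical comparisons between step
conditions and level locomotion. Because the original fluoroscopy
recordings are not publicly deposited, every input is produced by a
forward-kinematic gait simulator whose parameters are the published level
and step-condition values; the pipeline is validated by recovering those
values through the complete chain.

## The forward-kinematic gait generator

**Skeleton.** A bilateral chain pelvis → hip → knee → intertarsal joint
(INT, the avian ankle) → tarsometatarsal–phalangeal joint (TMP) → middle
toe tip (Mto), with 22 named landmarks: 15 kinematically meaningful points
(pelvis cranial marker `p_c`, plus hip, knee, two intertarsal markers, two
tarsometatarsus markers and the toe tip per side) and 7 filler markers
rigidly attached to existing segments. Segment lengths (femur 33.0 mm,
tibiotarsus 56.5 mm, tarsometatarsus 33.0 mm, toe 29.8 mm) keep quail-like
proportions and were scaled once so the effective leg (hip→Mto) is 0.130 m
at touchdown of the level gait, the value reported for level locomotion.
The straight-leg reach is 0.152 m, so all observed stance leg lengths
(0.08–0.15 m) are reachable.

**Gait templates.** Each of the seven conditions (level; 1/2.5/5 cm steps
up and down) carries the published spatiotemporal parameters (speed,
contact and swing time per leg role) and, for each angular variable
(hip flexion–extension in the β+90° reporting convention, whole-leg
mediolateral rotation α, ab-adduction γ, knee, INT and TMP included
angles), control values at the five analysis phases TD, 15 %, mid-stride,
TO and 85 %. Printed event values are taken verbatim (e.g. level hip
flexion 42° at TD, 41° at 15 %, 58° at TO; abduction 36°→18°;
mediolateral −14°→11°; knee 120/98/60; INT 125/112/112; TMP 158/143/142).
Periodic (level) trajectories are interpolated by the unique degree-2
trigonometric polynomial through the five control points; step-condition
trajectories use a clamped cubic spline. The trigonometric interpolant was
chosen over a periodic cubic spline because it is band-limited by
construction: with only M = 10 annotated frame pairs, the linear
landmark regressor can only generalize when the landmark signals stay
inside a ≈9-dimensional function space, and spline knots leak energy into
high stride harmonics. Every control value is still interpolated exactly.

Pelvis pitch, roll and yaw are mean + cosine harmonics: pitch oscillates
at twice the step frequency (4 cycles per stride, amplitude 1.5°) around a
mean of −10° (the ~10° retroversion of level locomotion; negative pitch =
retroversion); roll and yaw run one cycle per stride with small
amplitudes. A 5-point control table cannot represent the 4-per-stride
pitch oscillation, which is why the pelvis variables are parameterized
directly as harmonics.

**Unprinted values and calibration.** Mid-stride and 85 % control values,
the pelvis roll/yaw harmonics and the skeleton scale are not printed in
the study. They were calibrated once, offline, against four groups of
constraints evaluated on the simulated level gait: (i) printed emergent
targets — aperture angle 53° at the leading-leg touchdown and a 17° hip
extension excursion from the post-TD minimum to TO; (ii) ground
consistency — the stance toe tracks the terrain to ≲0.2 mm at eleven
stance phases; (iii) swing clearance ≥ 2.5 mm; (iv) minimal
out-of-subspace signal energy (the residual of the projected landmark
signals beyond a rank-9 + drift linear model), which bounds the tracking
stage's held-out error. The resulting defaults are frozen in
`quailkin.gait`; they are study conditions, not tuning knobs. Two
limitations follow: the swing toe clearance (~3 mm) is lower than a real
quail lifts its toe, and the emergent effective-leg angles at TD/TO
(≈51°/105°) sit inside the reported level ranges (40–55° and 85–110°) but
not at their printed centres (43°/108°) — with every joint angle pinned to
its printed value, the effective-leg angle is not independently
adjustable.

**Ground contact and pelvis height.** Each leg demands
"pelvis height = terrain + toe-height profile − (toe height relative to
the pelvis)". The toe-height profile is a degree-4 trigonometric bump
(product of four antiperiodic sine factors, squared) with double zeros
exactly at TD and TO, so the toe lands and lifts on quadratic flanks at
the nominal events and stays within a fraction of the apex during stance.
The pelvis blends the two legs' demands with a single-harmonic stance
weight (1 + 0.97·cos 2π(φ − mid-stance); the pair sums exactly to 2).
Everything in this construction is band-limited, and a per-frame vertical
shift of the whole skeleton changes no angle, so ground consistency costs
no kinematic fidelity. For step conditions the terrain shifts by the step
height between stride i−1 and i; the leading (right) leg contacts the
shifted plate first. Step-condition poses are not re-calibrated for
ground consistency, so their toe–terrain residuals are of centimetre
order; step trials therefore rely on the generator's ground-truth event
tables (mirroring the study's manual event digitization).

## Landmark localization (ε-SVR)

Per landmark and output coordinate (u, v in each of the two views — four
scalar models per landmark pair, 88 models for N = 22) a linear ε-SV
regressor is trained on M = 10 frame pairs sampled equidistantly over the
sequence (first and last frame always annotated) and used to locate the
landmark in all remaining frames. The solver is libsvm's SMO
(scikit-learn `SVR(kernel="linear")`) followed by an exact solve of the
KKT system on the identified active set, which removes the ~1e-5 primal
suboptimality the SMO stopping rule leaves; tests verify the objective
against an independent SLSQP solve of the primal program. Features are
standardized with training-frame statistics; targets are raw pixels.
Library-level hyperparameter defaults are C = 1, ε = 0.1 px; the
synthetic end-to-end pipeline configures C = 1e6, ε = 0.01 px because its
noiseless features admit near-interpolation.

The default feature source stands in for learned image features: a fixed
random orthogonal map (QR of a Gaussian matrix) of the concatenated
two-view pixel coordinates, plus an offset, optionally extended by
nonlinear sine distractor channels and per-channel Gaussian noise
(defaults: 8 distractors, 1 % of signal SD; the rig adds 0.5 px pixel
noise by default). The orthogonal map is invertible on the signal
subspace and has condition number 1; a generic dense Gaussian map is
ill-conditioned at D ≈ 88 and amplifies exactly the out-of-sample
component that the minimum-norm SVR solution cannot pin down from 10
frames. Any callable mapping a two-view observation pair to a
frames × D matrix can replace this source (the CNN features of the
original work are out of scope here).

## 3D reconstruction

Both views are 11-coefficient DLT cameras. Calibration solves the
linearized projection equations of ≥ 7 non-coplanar cube spheres by least
squares after centroid/scale normalization of the 3D and pixel
coordinates (an un-normalized solve agrees in the fitted projections; the
coefficient space itself is ill-conditioned). Triangulation solves the
four stacked ray equations per landmark and frame, records per-view
reprojection errors and the condition number, and never fills gaps: a
landmark missing in either view stays missing. The default rig emulates
the laterolateral and ventrodorsal beams: orthogonal optical axes, 1.5 m
source distance, 4500 px focal length (≈3 px/mm at the animal). On
noiseless data the calibrate → project → triangulate loop closes to
≤ 1e-9 m; with 0.5 px pixel noise the median 3D error is < 0.5 mm.

## Kinematics

Frames follow the study's construction: the pelvis frame sits at the
centroid of both hips and `p_c` (e_y from right to left hip, e_z ⟂ to the
e_x-interim/e_y plane); the whole-leg frame sits at the femur midpoint
with e_z from knee to hip and e_y the normal of the hip/knee/TMP-distal
plane, pointing left. Angles use the intrinsic Cardan z–x–y sequence
(R = Rz(γ)·Rx(α)·Ry(β)): γ = ab-adduction, α = axial/mediolateral
rotation, β = flexion–extension, reported for the hip as β + 90° because
pelvis and femur are orthogonal in the zero pose. Right-leg α and γ are
negated so both sides share the left-leg convention (`hip_angles(...,
left_reference=False)` keeps raw values for the stride pipeline's
mirroring step). The pelvis-against-global decomposition uses the same
sequence; whether the original analysis did is not stated — this is an
assumption. Near gimbal lock (|α| → 90°) a warning is raised and γ
absorbs the indeterminacy. Joint angles are included 3D angles at the
joint (the quasi-planar gait makes the difference to sagittal projections
small). The effective leg is the hip→Mto segment; its angle is measured
in the global sagittal plane from the forward horizontal (< 90° with the
toe cranial to the hip); the aperture angle is the 3D angle between the
two hip→Mto vectors. Velocities use second-order central differences
after an optional zero-phase 4th-order Butterworth low-pass at 25 Hz.

## Stride pipeline

Touchdown/toe-off detection is height-based: contact is entered below
0.8 mm above the terrain and left above three times that level, with
debouncing, and each boundary is refined by fitting a parabola to the
local flank and taking its root (the generator's toe lands on a quadratic
flank). The threshold is scaled to the generator's calibrated clearance;
a forward-speed gate is available but off by default because
prescribed-angle kinematics leave a residual stance skate. Supplied event
tables always take precedence. Strides are TD→TD per leg (level), or
TD→TD / TO→TO windows spanning the terrain shift for the trailing/leading
limb of a step trial; every stride is linearly resampled to exactly 100
points (0-based phase, "15 %" = index 15), missing spans stay missing.
Mirroring to the left-reference convention negates the x/z rotation
variables (hip α, γ; pelvic roll, yaw) of right-side trials. Event
windows are the event ± 4 samples (truncated and flagged at curve
boundaries): 15 % and TO for trailing strides, TD and 85 % for leading
strides.

## Statistics

Condition-vs-level comparisons treat the 9-sample event window as a
multivariate response (one-way two-group MANOVA, Wilks' λ), gated at
α = 0.05, with the pairwise statistic from a Levene-gated post hoc on the
window means; `response="mean"` switches to the univariate comparison.
The Levene test is Brown–Forsythe (median-centred). Homogeneous variances
select TukeyHSD (pooled variance, studentized range), otherwise
Games–Howell (Welch degrees of freedom per pair) — for two groups
Games–Howell reduces exactly to Welch's t-test, which the tests verify.
Within-animal effects of step height and direction use two-way
repeated-measures ANOVA with Greenhouse–Geisser correction and listwise
completion of subjects. Significance codes follow the four-star
convention ('****' p < 0.0001 … '*' p < 0.05). No correction is applied
across variables beyond the post hoc family, mirroring the study's
reporting. The CLI's `stats` command simulates a mini-study (default 8
individuals with stable per-animal angular offsets of SD 3° plus 1°
per-trial noise, the same animals reused across conditions so the
repeated-measures layer sees paired data).

## What the synthetic data does and does not show

The generator reproduces the published kinematic values, rigid-body
geometry, biplanar projection and event structure, and its defaults are
the study conditions. It does not emulate X-ray image formation, soft
tissue or marker occlusion, the CNN feature extractor, manual annotation
error, or between-stride variability within a trial (one template =
one periodic gait; variability enters only through the stats layer's
per-individual offsets). Passing recovery tests therefore demonstrates
the correctness of the analysis chain, not the field performance of the
tracking stage on real fluoroscopy images. Tracking accuracy in
particular depends on the band-limited design of the synthetic motion;
real deep features would behave differently.

## Numerical choices and problem sizes

Simulated trials default to two strides at 500 Hz (370 frames for the
0.37 s level stride); the statistics layer simulates at 250 Hz. The
recovery benchmark pools the stance-interior readings over every complete
TD→TD stride of both legs (three windows) and reads touchdown-event
values at the trial's first touchdown, which coincides with an annotated
frame. Orthonormality and recomposition tolerances are 1e-9; rigid-body
tolerance 1e-9 m; DLT degeneracy is declared below a relative singular
value of 1e-6; the triangulation condition number is reported, not
enforced. All randomness flows from a single root seed via fixed
per-stage offsets; identical configurations are bit-identical.
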