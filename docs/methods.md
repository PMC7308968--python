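# Methods

This note documents the models implemented in `gaitagree`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic cohorts
do and do not establish about real data.

## Angle constructions and sign conventions

All kinematics are planar, in the sagittal plane of the left leg, with `x`
the direction of progression and `y` up. A frame recorded while walking in
`−x` is mirrored before any signed computation (detected from ASIS being
behind PSIS), so flexion and dorsiflexion signs are independent of walking
direction. The constructions are invariant to translation, scaling and
in-plane rotation of the marker set, so pixel and metric coordinates give
identical angles.

- **Hip.** The pelvic line runs ASIS→PSIS; its *caudal* (downward)
  perpendicular through the greater trochanter is the reference ray, and the
  hip angle is the signed angle from that ray to the thigh line GT→LFC,
  positive anteriorly (flexion). Orienting the perpendicular caudally makes a
  vertical thigh under a level pelvis read exactly 0°. A consequence worth
  stating explicitly: anterior pelvic tilt (ASIS drops below PSIS) rotates
  the reference ray posteriorly, so the same lab-vertical thigh reads *more*
  flexed — the hip angle is a pelvis-relative, not a lab-relative, quantity.
- **Knee.** `180° − (inner angle at LFC between the GT and LM rays)`. The
  unsigned protractor angle cannot distinguish flexion from hyperextension,
  so a cross-product orientation test assigns the sign: shank posterior to
  the extended thigh line → flexion (positive), anterior → hyperextension
  (negative). A perfectly straight leg returns exactly 0.
- **Ankle.** `90° − (inner angle between the foot line CAL→MT2 and the shank
  line)`, signed so dorsiflexion is positive. Of the two complementary inner
  angles available, the implementation fixes the one measured against the
  *proximally* directed shank ray: that is the convention under which normal
  heel-strike posture (foot slightly plantar flexed) comes out negative, at
  around −8°, matching clinical reporting.

## Event detection

- **Force threshold.** Initial contact is the first sample of the vertical
  ground-reaction force at or above 20 N that *stays* at or above threshold
  for `min_above` consecutive samples. The persistence window (default 10
  samples = 10 ms at 1000 Hz) rejects isolated pre-contact spikes; the
  threshold value itself is the conventional force-plate criterion.
- **Kinematic surrogate.** Without a force plate, initial contact is taken
  as the first local minimum of heel-marker (CAL) height within a search
  window — an automated stand-in for an observer scrubbing video for the
  heel-strike frame.

Frames are 0-based everywhere, including exported CSVs.

## The synthetic cohort generator

The generator emulates a two-session, two-observer, two-system reliability
study: 50 subjects × 2 sessions (markers re-placed) × 5 repetitions ×
2 observers digitising the same videos × {video, 3D reference}. Each stage
has an explicit ground truth:

- **Subjects.** Stature and mass are drawn from N(167.5 cm, 25.6 cm) and
  N(65.7 kg, 12.9 kg) — the generator treats these as the target cohort's
  descriptive statistics — with rejection outside [140, 205] cm and
  [40, 120] kg (the stature SD is large, so the tails are clipped to
  plausible adults; rejections are logged). Segment lengths scale with
  stature using standard anthropometric fractions (thigh 0.245·h, shank
  0.246·h, foot 0.152·h). True IC angles are drawn per joint around
  (hip 33.06°, knee 4.55°, ankle −7.77°) with between-subject SDs
  (5.7, 3.8, 3.7)°.
- **Gait curves.** Each joint angle over the cycle is a sum of two harmonics
  plus a constant chosen so the curve passes *exactly* through the subject's
  drawn IC target at the IC phase. The harmonic shapes were least-squares
  fitted to textbook normal sagittal gait curves; only the shape matters
  (the constant is re-anchored per subject). Two harmonics caricature rather
  than reproduce real curves — the knee's double flexion wave is smoothed —
  but they are smooth, periodic and analytically differentiable, which the
  frame-shift error bookkeeping uses.
- **Pose and ground contact.** A planar pelvis–thigh–shank–foot linkage
  realises the four curves (pelvic tilt, hip, knee, ankle). The pelvis height
  is not free: it is set so the nominal heel marker follows a designed
  clearance curve whose minimum (zero) falls exactly at the IC phase. Joint
  angles are unaffected (the constraint is a pure vertical translation), and
  heel strike is by construction the local minimum of heel height, as in real
  gait — which is what the kinematic event detector keys on.
- **Camera.** Pinhole model: 50 fps, 1280×720, focal length 1000 px, placed
  2.5 m lateral and 1 m above the floor, optical axis perpendicular to the
  sagittal plane. Perspective division is the mechanism by which the elevated
  camera distorts the view of the sagittal plane; an orthographic mode (same
  in-plane scale) is the distortion-free limit and is what perspective
  converges to as the camera recedes. The perspective default contributes a
  systematic video-vs-reference offset of roughly +0.5° on the knee.
- **Error model** (all angle-space consequences emerge mechanistically):
  - `sd_session_m` = 3 mm marker re-placement per session, frozen across that
    session's repetitions, applied in each marker's segment frame;
  - `sd_observer_frame` = 1 frame of IC frame-selection error per observer per
    trial (rounded to integers), which maps to angle error through the curve
    slope at IC (≈ 0.9°/frame hip, 0.4 knee, 1.0 ankle at 50 fps);
  - `sd_digitize_px` = 1.2 px of marker-click jitter per observer per trial;
  - `sd_residual_deg` = 1.5° stride-to-stride variation of the true IC angles;
  - `system_bias_deg` = (+0.87, +1.54, −1.18)°: the additive part of the
    video-vs-reference offset. Together with the perspective distortion the
    *total* default bias is ≈ (+0.8, +2.0, −1.3)°;
  - `sd_reference_deg` = 0.5° measurement noise of the emulated 3D reference.
    The reference system is emulated as ground truth minus the system bias
    plus this noise — it is *not* a re-implementation of a full 3D
    biomechanical model.
- **Randomness.** One seed drives everything through hierarchical
  `SeedSequence` substreams keyed by (subject, session, repetition,
  observer), so identical configurations are byte-reproducible and enlarging
  the cohort never perturbs existing subjects.

**Calibration.** The session/digitisation/frame defaults were chosen once, by
delta-method bookkeeping (`implied_error_variances`), so that a default
cohort lands in the reliability regime typical of marker-assisted video
goniometry: intra-rater ICC in the high 0.8s with ±5° limits of agreement,
inter-rater ICC above 0.95 with ±2° limits, and the biases above. The
magnitudes of the underlying physical error components are themselves
assumptions (placement error ~3 mm, clicks ~1 px, frame picks ~1 frame), not
estimates from data; only their statistical consequences are constrained.

**Aggregation.** Reliability contrasts operate on the mean of the 5
repetitions per (subject, session, observer, system) — the least-variance
choice; `median` and `first` (a single selected repetition) are available.

## Agreement statistics

- **ICC.** Two-way decomposition with subjects as rows; single-measures
  absolute agreement `(MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE))` is the default
  (it charges systematic rater offsets to error, which is what a method-
  comparison question needs); the consistency form is also computed and both
  are reported. Confidence intervals use the standard F-based formulas
  (Satterthwaite df for the absolute form). Interpretation bands: poor <0.5,
  moderate 0.5–0.75, good >0.75 to 0.9 inclusive, excellent >0.9.
- **Bland–Altman.** Bias and `±1.96·SD` limits (the conventional multiplier,
  not a t quantile); per-pair means/differences are retained as plot data.
  Difference orders are fixed and documented: session1−session2,
  observer1−observer2, video−reference.
- **LoA reconstruction.** From a published mean difference and its 95% CI,
  `SD(d) = (CI half-width)/t₀.₉₇₅,ₙ₋₁·√n`, limits `MD ± 1.96·SD`. This is a
  consistency check on published tables: it assumes the CI was t-based with
  n−1 df and inherits the table's rounding (worth ~0.1°). Note that published
  agreement tables are not always internally consistent — for the study
  design this package models, only the knee row reconstructs; applying the
  identity to the hip and ankle rows exposes arithmetic inconsistencies in
  the source numbers, so those are deliberately not regression targets.
- **Paired t.** Mean difference with t-based CI and two-sided p. Degenerate
  zero-variance differences are flagged: p = 1 at zero mean difference, p
  reported as 0 (below machine precision) otherwise.
- **Sample size.** The Walter–Eliasziw–Donner closed form with one-sided α;
  attrition is applied multiplicatively (`ceil(n0·(1+a))`). With ρ0=0.6,
  ρ1=0.8, k=2, α=0.05, power 0.8 this gives n0=39 and 43 after 10% attrition.
- **Multiplicity.** No multiple-testing correction is applied across joints
  or contrasts; reports state per-comparison p values.

## Numerical decisions

- Angles come from two-argument arctangents of cross/dot products — stable
  near collinearity; coincident construction markers raise rather than
  returning garbage.
- ICC confidence intervals collapse to the point estimate when the residual
  mean square is zero relative to the signal (< 1e-12·max(MSR, MSC)): the
  F-based formulas are undefined there, and the estimate itself is exact.
  An all-constant matrix has no defined ICC and is returned flagged.
- CSV readers use round-trip float parsing so write→read is bit-exact;
  reports embed the seed and a config hash, and identical runs are
  byte-identical.
- The anthropometry sampler resamples out-of-range draws (with a logged
  warning) rather than truncating, keeping the in-range distribution shape.

## What the synthetic tests do and do not show

Passing tests establish that the statistics are computed correctly (verified
against an independent ICC implementation and closed forms), that the angle
constructions invert the forward model exactly, and that the pipeline's
estimates track known variance components (closed-form vs estimated ICC
agree within ±0.02 on large cohorts; CI coverage is nominal within ±2%).
They do *not* validate the error model against real videos: real digitisation
error is not isotropic Gaussian, marker re-placement errors are correlated
across markers, soft-tissue artefact is absent, gait curves are idealised
two-harmonic shapes, and the 3D reference is emulated rather than modelled.
Conclusions about any particular real system require real paired recordings.

## Known limitations

Left limb, initial contact and the sagittal plane only; no markerless pose
estimation; no smoothing by default (an optional moving average is provided
but off); ICC forms limited to single-measures (no average-measures ICC(·,k));
no regression-based or non-parametric limits of agreement.
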