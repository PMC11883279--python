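# Methods

This note documents the models, estimators and numerical choices behind
`saltijump`, what the synthetic-data generator does and does not emulate,
and the known limitations of each component.

## Coordinate frame and units

World coordinates are millimetres with *x* pointing from the take-off
platform toward the landing platform and *y* up; the origin is the CoM
position at movement onset, so trajectories start at (0, 0).  Time is in
milliseconds (0.2 ms per frame at 5000 frames/s), which makes mm/ms
numerically equal to m/s.  Raw digitizer files are in pixels (optionally
with an image y-axis pointing down); the reader applies the mm-per-pixel
scale and, when asked, the y flip, and records both in the trial's
provenance.  Body mass is in mg; the derived panel is reported in µJ
(energy), mN (force), mW (power) and multiples of g = 9.81 m/s²
(exactly; not a measured local gravity).

## Event detection

**Movement onset.**  The tracking-noise floor σ is the standard deviation
of the frame-to-frame CoM displacement over a pre-trigger baseline window
(default 50 frames).  Onset is the first frame whose displacement exceeds
k·σ (default k = 3) for a sustained run (default 5 frames).  On noise-free
tracks σ = 0 and the first nonzero displacement triggers.  Because a real
stance phase starts from zero acceleration, the CoM moves imperceptibly
for the first few ms, so under tracking noise this detector is *late* by
however long the jump takes to move the CoM ~kσ per frame; it is never
early.  Detected take-off durations from noisy tracks are accordingly
conservative (shorter), and the amount depends on the noise level and the
acceleration ramp — on noise-free data the bias is zero.  The thresholds
are exposed in the run config.

**Per-leg lift-off.**  A leg has lifted off at the first frame where its
tarsal claw sits more than a height threshold (default 0.05 mm) above the
take-off surface for 3 consecutive frames.  A leg held raised for the
whole trial "lifts off" at frame 0; a leg that never leaves the platform
raises a no-lift-off error.  All-legs-off is the latest lift-off among
legs that were on the platform after onset.  For CoM-only trials (no leg
tracks) the end of stance falls back to the first sustained non-positive
path acceleration after the peak (ballistic deceleration), which on
simulated jumps agrees with the scheduled end of stance to a frame.

**Abdomen-movement baseline.**  The take-off angle is defined from the
frame before the abdomen moves.  The pipeline does not track the abdomen
separately and uses the frame before CoM onset, which precedes any body
movement and therefore satisfies the definition.

## Differentiation and the acceleration peak

Speed is the scalar norm of the per-frame CoM displacement divided by the
frame interval ("path speed", computed for every frame); acceleration is
the first difference of speed.  No smoothing is applied by default; an
optional centred moving-average window (recommended 5 for noisy tracks)
is available, because raw double differencing at 0.2 ms amplifies
coordinate noise by ~√2/Δt² and is logged when used.

The first-difference estimator reports, at each sample, the *average*
acceleration over one frame interval.  The stance profile family used by
the simulator (and, generically, any jump whose acceleration peak is a
corner rather than a smooth quadratic maximum) is therefore read ~1–2%
low at the peak: the bias is ≈ (Δt/8)(s₋ + s₊), with s∓ the slopes of
a(t) on either side of the peak.  Velocity, duration and angle carry no
such bias.  This is a property of the estimator the panel is defined
with, not a defect to be corrected by fitting the known profile; the
parameter-recovery tests bound acceleration at 2% and everything else at
1% (duration: two frame intervals).

Maxima of speed and acceleration are taken inside the take-off window
[onset, all-legs-off]; argmax ties resolve to the earliest frame.

## Synthetic jumps

The generator is prescribed-kinematics: it reproduces the observable CoM
and leg kinematics without modelling the hydraulic mechanics that produce
them (no force balance, no pressure dynamics, no silk drag line, no
landing).  One trial consists of

1. a stationary baseline (default 20 ms, giving the detector its noise
   window),
2. a stance phase in which the CoM moves along the straight line at the
   take-off angle with acceleration magnitude
   a(t) = A (t/t_p)^p for t ≤ t_p, then a linear descent to 0 at T,
   where t_p is a fixed fraction of the stance (default 0.85) and the
   exponent p is solved in closed form so that ∫a dt equals the take-off
   velocity — this reconciles the three stance statistics (peak
   acceleration, take-off velocity, duration) that jump studies print,
   which no single-parameter profile can match simultaneously.  The
   requested triple must lie in the attainable interval
   (A(1−f)T/2, A(1−f)T/2 + A f T); anything else raises a feasibility
   error that reports the interval,
3. ballistic flight at −9.81 m/s² vertical, sampled until the horizontal
   displacement spans the 40 mm platform gap plus a short margin.

The waveform family itself is a modelling choice (real stance waveforms
are not published for these animals); it is exposed through
`peak_fraction` and produces a corner peak, which is the conservative
case for the peak-acceleration estimator (above).

**Legs.**  Each leg is a planar chain of three equal-length rigid
segments anchored to the body frame.  Legs I and II are raised and fully
extended from frame 0 (they play no propulsive role and are held in front
of the body).  For stance legs (III and IV) the ELL is interpolated
linearly in time from its initial value (default 0.35) to 1.0 at the
scheduled full-extension time; each frame the claw is placed on the
platform (y pinned, x free) at the chord distance ELL·L from the
trochanter, and the two middle joints sit symmetrically above the chord
(a closed-form fold that keeps all three segment lengths exact for any
chord).  At the scheduled lift-off the pose freezes relative to the body
and translates with it.  Default schedule: leg IV fully extends 1 ms
before the acceleration peak and lifts off at the peak; leg III extends
until the end of stance and lifts off last.  For female-mean parameters
the peak fraction is placed so the scheduled III-after-IV lag equals the
observed female mean of 3.5 ms.  Anchors and segment lengths are
synthetic morphometry chosen at salticid scale (leg III longest), not
measured values.

**Noise.**  Manual-digitization jitter is modelled as i.i.d. zero-mean
Gaussian noise per coordinate (default off; the validation suite uses
0–0.03 mm).  Real digitization error is not white — it has outliers,
frame-to-frame correlation and landmark-dependent magnitude — so passing
noise tests here bound only the white-noise behaviour.

**Study generator.**  `simulate_study` draws body mass per subject and
take-off statistics per jump around the published sex means (mass s.d.
from the study; kinematic spreads chosen to bracket the published
per-sex ranges), resampling until feasible, and by default reproduces
the study's shape: 10 males × 3 jumps and 12 females with one
contributing two, i.e. 30 + 35 jumps.

What the generator does *not* emulate: out-of-plane motion and camera
perspective, leg occlusion and dropped frames (missing data is tested
through the reader, not the generator), non-straight stance paths,
wind-up body movements before onset, and any force-level physics.
Recovery tests on these data therefore validate the estimators'
numerics and the event logic, not robustness to those real-world
artefacts.

## Choreography descriptors

ELL divides the trochanter-to-claw chord by the summed reference segment
lengths.  The reference lengths default to the 95th percentile of the
per-frame inter-joint distances over the trial (robust to noise, no
morphometry needed) and can be overridden with measured values.  Noise
can push ELL slightly above 1; values are retained and flagged beyond
1.05.  The joint angle is the interior angle at the femoro-patellar
joint, in [0, 180]°; coincident adjacent joints yield a missing value
with a warning.  Maximum-ELL timing uses the *first* frame attaining the
maximum (within 1e-9 relative), so a plateau at full extension dates
from when extension completes.  Chronologies are aligned to the
per-trial acceleration peak.

The propulsive-leg call requires both (a) last lift-off and (b) maximum
ELL after peak acceleration; when they disagree the (b) leg is returned
with a conflict flag, and when no leg satisfies (b) the call is
explicitly inconclusive rather than an error.  Only the camera-facing
legs are analyzed (profile-view filming).

## Circular statistics

Take-off angles are summarized by the circular mean and mean resultant
length r; the reported spread is the circular s.d. √(−2 ln r).  The
Watson–Williams two-sample F statistic is
K (N−2)(R₁+R₂−R)/(N−R₁−R₂) with df (1, N−2), with
K = 1 + 3/(8κ̂) and κ̂ the standard piecewise maximum-likelihood
approximation from the pooled within-group mean resultant length
(2r̄ + r̄³ + 5r̄⁵/6 below 0.53; −0.4 + 1.39r̄ + 0.43/(1−r̄) to 0.85;
1/(r̄³ − 4r̄² + 3r̄) above).  The test assumes concentrated samples; a
flag is attached when r̄ < 0.75.  Fully degenerate inputs (no
within-group dispersion) return F = 0 with a note.  Calibration at the
study's design point (κ = 20, n = 30 per group) puts the type-I error at
α = 0.05 within [0.035, 0.065] over 2000 replicates, with power > 0.9
for a 15° mean shift.

## Mixed models and rank tests

Kinematic responses are modelled as
response ~ mass + sex (+ mass:sex) with subject random intercepts,
fitted by maximum likelihood (statsmodels `MixedLM`); ML rather than
REML because the AIC comparison is between models that differ in fixed
effects.  AIC is computed as 2k − 2 logL with k = fixed effects + 2
variance parameters; ties (to 1e-9) go to the reduced model.  Responses
are natural-log transformed by default (jump energetics scale
multiplicatively with mass); the transformation and the
denominator-degrees-of-freedom method are recorded in every fit.
Fixed-effect F tests are Wald tests with a containment approximation for
the denominator df (n_subjects − n_fixed); a Satterthwaite correction is
not available in the backend, and the containment choice is deliberately
conservative for between-subject effects.  Null simulations with 20
subjects put the sex-effect type-I error in [0.03, 0.08] at α = 0.05.

Mann–Whitney U uses midranks for ties and U = min(U_a, U_b).  For pooled
n ≤ 20 the two-sided p is exact, by enumerating all C(n, n_a) labelings
of the pooled midranks and counting U as extreme as observed; beyond
that, a tie-corrected normal approximation with continuity correction.

## Centre of mass

The voxel route takes the unweighted mean of included-label voxel
centres (voxel (i,j,k) is centred at (i,j,k)·spacing), scaled by the
per-axis spacing — uniform density inside the included labels, per the
homogeneous-body assumption; legs are excluded by passing only the body
label.  The mesh route integrates signed tetrahedra against the origin
over a watertight, consistently oriented triangle mesh; watertightness
is checked fail-closed (every directed edge exactly once, with its
reverse present), and inward-oriented meshes are handled by the sign of
the total volume.  The two routes agree within half a voxel on
voxelized/meshed versions of the same solid.  Resolution halving uses
majority-label binning over 2×2×2 blocks with ties to the lowest label
and zero-padding (with a warning) for odd dimensions.  No segmentation
or mesh repair is performed here — inputs are assumed already labelled
and clean.

## Pipeline and reproducibility

All thresholds, statistics options and the master seed live in a single
`RunConfig`; every output file's first comment line embeds the package
version and a SHA-256 hash of the config, and reruns with the same
config and seed are byte-identical.  Per-trial analysis failures are
isolated, logged with the reason, and reported in the run summary (CLI
exit codes: 0 ok, 1 partial, 2 fatal).  Sex-level summary panels are
means of per-jump values (angles summarized circularly), matching how
per-jump panels are conventionally averaged — note that derived
quantities of mean inputs differ from means of derived per-jump values
for nonlinear panels (force, power), which is why those cells are not
expected to be reproducible from printed sex-mean inputs.

## Problem sizes used in validation

The validation suite simulates single jumps of ~450–470 frames, studies
of 65 jumps, 2000-replicate circular-test calibrations, 200-replicate
mixed-model calibrations, and 100³-voxel volumes — sizes chosen to match
the study design where one exists (subjects, jumps, sample sizes per
group) and otherwise to keep Monte-Carlo error comfortably inside the
asserted bands.
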