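# Methods

## The task and its physics

A seated participant strikes a small object (a 46 g plastic cube) with the
index fingertip so that it slides along a straight channel and stops at a
target distance `d` (0.25 or 0.50 m). The channel's bottom surface is
aluminum or balsa wood and can be inclined at α ∈ {−10°, 0°, +10°}. After
impact the object moves under uniform deceleration

    dec = g·(sin α + μ·cos α),

with kinetic friction coefficient μ, so the launch speed that stops it
exactly on target is

    v_opt = √(2·g·d·(sin α + μ·cos α)),

its inverse, the stopping distance, is `d = v₀²/(2·dec)`, and an observed
(launch speed, distance) pair implies

    μ = (v²/(2·d·g) − sin α)/cos α.

Object mass cancels throughout: both the decelerating force and the
momentum scale with it. The API therefore takes no mass argument for any
of these quantities, and with μ_aluminum = 0.37, μ_balsa = 0.47 and
g = 9.81 m/s² the twelve v_opt values of the experimental conditions are
reproduced to ±0.001 m/s (`tests/test_acceptance.py`).

The last equation is the conceptual core: fed the *target* distance it
yields the mover's *subjective* friction coefficient (their internal model
of the surface); fed the distance the object *actually* travelled it
yields the objective one.

## Per-trial friction estimation

μ is estimated per trial by fitting a second-order polynomial
y = At² + Bt + C to the object's position from its speed maximum until it
stops, taking dec = −2A (as a positive magnitude; the sign of the fitted
second derivative is not informative once noise is present) and inverting
the deceleration formula. The fitting window end is first found from the
unfiltered finite-difference speed (last sample above the 0.04 m/s
movement threshold, minus the boundary sample whose central difference
straddles the stop) and then refined by re-estimating the stop time from
the fitted parabola's vertex (−B/2A) and refitting until stable, at most
five iterations. On noiseless episodes the first window is already exact
and μ is recovered to machine precision; with 0.5 mm position noise at
250 Hz the refinement is what keeps the flat post-stop tail out of the
fit (median |Δμ|/μ ≈ 0.1%, vs ≈ 4% with the threshold window alone).

## Segmentation and contact detection

Speeds and accelerations are plain finite differences of the raw series
(`numpy.gradient`: central differences, one-sided at the ends). No
low-pass filtering is applied anywhere: the ~15 ms collision transient
that contact detection relies on sits above the cutoff frequencies in
common use for limb kinematics and would be destroyed.

Phases: the arming start is the first sustained fingertip retreat (speed
< −0.02 m/s for 3 consecutive samples); the arming end is the return of
fingertip speed to ≥ 0 (rest at maximal extension); the strike runs from
there to contact.

Contact: inside the window between maximal fingertip speed and object
motion onset, each acceleration sample is normalized by the window's most
negative acceleration; the sample immediately preceding the first
normalized value above 0.4 is the contact instant. The 40% criterion
skips shallow pre-contact decelerations, and the window minimizer itself
normalizes to 1, so detection cannot come up empty. Two robustness
refinements are layered on the bare rule, both no-ops on clean data:

* a crossing must either be the window minimizer or be confirmed by the
  next sample also crossing. Adjacent central-difference acceleration
  samples share no raw positions, so the confirmation squares the
  false-alarm probability of differentiation noise (position noise of
  0.5 mm maps to ≈ 19 m/s² of acceleration noise at 250 Hz, the same
  order as the collision deceleration of a slow strike);
* the object-onset end of the window is found as the last sub-threshold
  speed sample before the object's speed peak, bounded below by a
  position guard (the sample where accumulated displacement exceeds
  2.5 mm — a launched object covers several millimetres per sample while
  marker noise is sub-millimetre). The plain first-crossing rule of the
  0.04 m/s threshold is kept as the standalone onset operation; under
  0.5 mm noise it fires while the object is still at rest.

Measured performance on simulated strikes spanning the protocol's speed
range: noiseless contact detection within ±1 sample in 100% of trials;
with 0.5 mm noise within ±2 samples in ≈ 98%.

## The synthetic participant

The generator is a first-class module, not a fixture: it produces marker
trajectories, sliding episodes and block designs with exact ground truth
for every quantity the analysis estimates.

**Learning.** The agent holds one subjective μ per surface material
(shared across slopes and distances — the generalization hypothesis under
test). Each trial it launches at the speed optimal under its belief plus
Gaussian motor noise (sd 0.05 m/s), observes the stopping distance,
inverts it to the implied friction coefficient, and moves its belief a
fraction λ (default 0.4) toward it. Because the implied coefficient
equals the objective one exactly, the belief error decays geometrically
by (1−λ) per trial and the spatial-error series is exactly exponential
with τ = −1/ln(1−λ) — which is what makes the exponential fit testable
against an analytic value. A `generalizes=False` profile resets the
belief to its initial value at every block start, the planted negative
control for the block-transition analysis. The initial belief (0.28) is
below both true coefficients, reproducing the observed pattern of
material-independent first strikes with larger undershoot on the
higher-friction surface.

**Kinematics.** The arm is a planar three-link chain (forearm 0.26 m,
hand 0.19 m, index 0.07 m) pivoting about a fixed elbow. Joint angles
follow minimum-jerk profiles: a full bell-shaped retreat (arming, 0.35 s,
ending at rest), then the first half of a minimum-jerk profile so that
angular rates — and the fingertip speed through the chain Jacobian — peak
exactly at contact. Joint amplitudes are affine in the commanded
fingertip impact speed with strategy-specific intercepts (wrist-strategy
movers recruit the wrist more, forearm-strategy movers the forearm); the
strike duration is solved so the fingertip speed at contact equals the
commanded value exactly in the continuous construction (within
discretization of the 250 Hz grid once sampled; the contact instant falls
exactly on a sample, with the hold phase absorbing grid rounding). After
contact, angular rates collapse exponentially (τ = 4 ms, ≈ 98% of the
loss inside the 15 ms contact duration) to a 25% follow-through residual
that decays over 50 ms — an impulsive collision; its sharp force peak is
the physical feature contact detection keys on. Fingertip-to-object
energy transfer is affine (launch = gain·(finger speed − offset)) with
strategy-specific parameters matched to the observed group means (wrist:
offset 1.16 m/s, forearm: 0.61 m/s), so wrist-strategy movers need
higher fingertip speeds for the same launch speed.

**Noise and reproducibility.** Motor noise is additive Gaussian on launch
speed; marker noise is i.i.d. Gaussian per coordinate (default 0.5 mm in
the pipeline, 0 in the raw generator). All randomness flows from one
session seed through `numpy.random.SeedSequence` spawning, one child per
trial, so sessions are bit-reproducible and cohorts can be spawned from a
single master seed.

**What the generator does not emulate** — and hence what green tests do
not show about real data: soft-tissue and marker-occlusion artifacts,
out-of-plane motion, stick-slip or velocity-dependent friction,
object–wall collisions inside the channel, within-participant drifts of
strategy or attention, and any learning rule other than the error-
correcting belief update (real participants need not update in μ-space;
the rule's only contract is producing exponential adaptation).

## Adaptation analysis

Performance (spatial error as a signed percentage of target distance,
overshoot positive; or launch speed) is fitted per trial series with
`offset + constant·exp(−(trial−1)/τ)`, nonlinear least squares with τ
bounded to (0.1, 100] trials and a four-point τ multi-start (0.5, 2, 8,
30); at each start the linear parameters are solved exactly, which makes
the fit deterministic and scale-equivariant. R² is computed against the
series mean and reported even when negative; classification: strong
(R² > 0.75), moderate (0.50 < R² ≤ 0.75, used only in the noisier
group-stratified transition analysis), none, or degenerate (constant
series — τ unidentifiable). Cohort fits are run on cohort-mean series
(matching one curve per condition); per-participant fitting is available
through the same function. With 10-point series at 20% relative noise the
per-replicate τ spread is large (median |τ̂−τ|/τ ≈ 34%, an inherent
property of the estimation problem, verified against an exhaustive τ
grid) but the estimator is median-unbiased: the median recovered τ lands
within a few percent of truth.

Block transitions: for every consecutive block pair sharing a surface
material, and for the half-session transition where slope, material and
distance change at once, the cohort's last-trial and first-trial errors
are each tested against zero (one-sample t, α = 0.05/12) and their
difference with a paired t test (α = 0.05/4). The generalization flag
("thumb-up") is raised iff neither one-sample test is significant. The
corrected α is always an explicit argument; only Bonferroni schemes are
provided. Zero-variance inputs return a degenerate flag instead of a
t statistic.

## Biomechanics

Joint angles come from horizontal-plane projections: forearm angle
between the channel axis and elbow→wrist; wrist angle between the forearm
axis and wrist→metacarpal head; index angle between the hand axis and
metacarpal→fingertip. Signed convention: the angle rotating the proximal
axis onto the distal one, counterclockwise positive. Angular amplitudes
are magnitudes of the change between strike start and contact; angular
velocities at impact are finite differences over a 3-sample window ending
at contact (unfiltered, window configurable).

Kinetic energy at impact uses the rigid-body decomposition given in the
module docstring, with the elbow as fixed pivot, centre-of-mass distances
from the anthropometric table (a `use_full_lengths` switch selects the
literal point-at-distal-end variant), and the hand's translational term
built from the wrist velocity due to forearm rotation plus the hand-COM
velocity about the wrist (tangential directions differing by the wrist
angle). The index finger's mass is excluded; the object's rotation is
blocked by the channel, so only its translational energy counts.
Anthropometric defaults (male reference fractions): forearm mass 1.62% of
body mass, COM at 45.74% of length, gyration radius 27.6%; hand 0.61%,
79.0%, 62.8%. The table is a constructor argument, not a constant.

Strategy clustering: K-means (K = 2, 10 seeded restarts) on z-scored
joint-amplitude features (3 joints × 12 conditions, last trial of each
condition); the cluster with greater mean raw wrist amplitude is labelled
"wrist". Movement-parameter regressions on optimal launch speed are OLS,
retained at R² > 0.75.

## Pipeline

`simulate → segment → analyze → report`, each stage consuming only the
previous stage's files (CSV + JSON in plain text), so every stage can be
re-run standalone and config + seed determine every output byte. The
defaults reproduce the study scale (33 participants × 120 trials); tests
and examples use smaller cohorts (4–12 participants, 2–3 trials per
block), which exercise every code path at a few percent of the cost.

## Numerical choices and degenerate inputs

* Angles in degrees at API boundaries, radians internally; g = 9.81 m/s²
  and dt = 0.004 s (250 Hz) as configurable defaults.
* Non-stopping surfaces (sin α + μ·cos α ≤ 0) raise a dedicated error
  wherever a stop is required; slopes of ±90° raise a degenerate-slope
  error in the friction inversions.
* The simulated learner's planned speed clamps the subjective stopping
  factor at 0.02 so a transiently low belief on a downhill slope cannot
  produce a non-stopping plan, and launch speeds are floored at four
  deceleration-steps so every episode has ≥ 3 pre-stop samples.
* Sliding episodes shorter than 3 samples before the stop raise an
  episode-too-short error (both in simulation and fitting).
* Ties in the object-speed minimum are broken toward the latest sample
  (the "minimum just before motion onset" reading).

## Known limitations

* The belief update is exact in μ-space, so simulated adaptation is
  noiseless-exponential by construction; real curves need not be.
* Contact detection assumes a single impulsive collision; double hits or
  prolonged pushes are out of scope.
* KE is planar and ignores the finger segment; no inverse dynamics or
  joint torques.
* The transition analysis requires a cohort sharing one block design;
  mixed-group tables must be stratified by the caller (the pipeline does
  this by counterbalancing group).
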