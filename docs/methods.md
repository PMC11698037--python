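# Methods

This note documents the models, estimators and numerical choices behind
`glidekin`, in the order the pipeline applies them, together with the
reasoning behind the design decisions that were genuinely open.

## Coordinate and unit conventions

All analysis happens in the lateral (vertical) plane: `x` horizontal,
positive toward the landing target; `z` vertical, positive up. Height
*losses* are reported as positive numbers. File I/O uses the units the
source data are reported in (cm for positions, mg for mass, mm² for area);
physical computations run in SI; angles are reported in degrees and
computed in radians.

Angles: glide angle θ is the direction of the CoM velocity below the
horizontal (`θ = atan2(−v_z, v_x)`; 90° is a pure vertical fall; values
above 90° mean backward drift and are preserved, not clamped). Body pitch β
is the head-to-abdomen axis against horizontal, positive nose-up — the sign
is anchored by the fact that a nose-down pitch during glide initiation must
come out negative. Body angle of attack is α = θ + β identically; the
identity is exact by construction and re-derivable bitwise from stored θ
and β.

## Smoothing and differentiation

Tracked head/abdomen coordinates are smoothed per coordinate with a quintic
smoothing spline whose **sum of squared residuals is bounded by a
tolerance** (`scipy.interpolate.UnivariateSpline(k=5, s=tol)`), the same
tolerance semantics as the classic spline-smoothing routines used for
digitised kinematic data. The default tolerance is 0.5 cm² per coordinate
per trial; a tolerance of 0 gives an interpolating spline, appropriate for
noise-free synthetic tracks.

For data with a known tracking-noise level σ the right budget is the
discrepancy-principle value `n·σ²` (the expected residual sum of the true
trajectory), exposed as `noise_matched_tolerance`. This matters: with
σ = 0.3 cm tracks, a 0.5 cm² budget forces the spline to chase noise and
the twice-differentiated acceleration series becomes useless for landmark
detection, while the matched budget keeps the glide-initiation time stable
to within three samples across noise realisations.

Velocity, acceleration and jerk are the spline's analytic first, second and
third derivatives — the splines were fitted precisely so that no finite
differencing of noisy samples is ever needed. A quintic (not cubic) order
keeps the third derivative continuous for the vertical-jerk series. The
first and last two samples of each trial are flagged and excluded from
landmark searches (spline edge effects).

## Lift/drag decomposition

With `a_tot` the measured CoM acceleration and `g = (0, −9.81) m/s²`,
the aerodynamic acceleration is `a_air = a_tot − g`. Drag is its projection
onto `n_D = −v̂`; lift onto `n_L`, the +90° rotation of `v̂` sign-fixed to
have a non-negative vertical component, so lift that supports weight is
positive and the direction cannot flip mid-trial during normal descent.
Reported invariants, asserted on every analysed trial: `n_D ⊥ n_L`, unit
norms, `a_D² + a_L² = |a_air|²`, and exact reconstruction
`a_D·n_D + a_L·n_L = a_air` (all to 1e-12 relative).

L/D is reported as the ratio of component accelerations (equal to the force
ratio; mass cancels). Samples where `a_D ≤ 0` — possible under noise, or
briefly during strong manoeuvres — yield a null L/D rather than a negative
ratio, and are counted in the log.

## Phase landmarks

*Terminal speed*: descent speed `u_z = −v_z` from the smoothed series; the
landmark is the **first** crossing of `0.95 · max(u_z)` over valid samples.
The 0.95 fraction is configurable (`terminal_fraction`). An all-ascending
trial returns an explicit null with a warning.

*Glide initiation*: the time of maximum horizontal acceleration, searched
from the terminal-speed landmark onward by default (glide initiation always
follows terminal-speed attainment; searching globally is a config option).
Exact ties break to the earliest time. If `a_x` never exceeds zero, the
landmark is null — heavier individuals can reach the floor while still
parachuting, and the output format keeps such missingness explicit.

*Segmentation*: pre-terminal → parachuting → initiation (a 0.16 s window
ending at the `a_x` peak, the observed nose-down interval; configurable) →
gliding. Landing statistics are means over the final 0.2 s.

## Pitch-oscillation statistics

**Peaks.** The pitch series is low-pass filtered (zero-phase second-order
Butterworth, 10 Hz cutoff by default — well above the few-Hz pitch modes,
well below the 25 Hz Nyquist of 50 Hz tracks) and extrema of
`β − baseline` with ≥ 1° prominence are collected, enforcing strict
maximum/minimum alternation. The baseline is the mean of the final 20% of
the analysis window (post-settling), since no explicit equilibrium
reference is available per trial.

**Damping ratio.** The gliding equilibrium pitch drifts during the
oscillation (β_eq = α_trim − θ(t) while θ is still shallowing), so
amplitudes measured against any fixed baseline are biased. The estimator
therefore uses **half-cycle swing amplitudes** — half the difference
between successive alternating extrema — which cancel slow drift exactly
and, on an ideal damped sinusoid, contain the pure decay factor:
δ = 2·mean ln(S_i/S_{i+1}), ζ = δ/√(4π² + δ²). The swing sequence is
truncated to the contiguous run ≥ 10% of the largest swing; without this,
residual noise wiggles after settling form near-constant swings that dilute
the decrement toward zero (with 0.5° angle noise the bias reaches a factor
of four). Growing oscillations give negative δ and negative ζ, reported
as-is and never clamped. The estimator is exact (ζ error < 1e-9) on
analytic amplitude sequences and recovers ζ to ±0.02 from sampled
noise-free responses at 50 Hz.

**Frequency.** Baseline-removed, Hann-tapered, 4× zero-padded FFT; the
reported value is the spectrum argmax above a 0.5 Hz low cut. For an
underdamped response this is the *damped* frequency; the undamped value
f_peak/√(1−ζ²) is reported alongside when ζ is available. Caveat: the
taper assumes the oscillation lies inside the analysis window (the pipeline
centres its window on glide initiation); a ring-down confined to the very
edge of a long window is suppressed by the taper and the estimate becomes
noise-dominated. A short, strongly damped ring-down (ζ ≈ 0.23 at ~5 Hz
decays within ~0.15 s) carries only ~1.5 visible cycles, so the spectrum
peak has an intrinsic width of ~1 Hz; under 0.5° angle noise the estimate
scatters by roughly ±0.1–0.2 Hz regardless of padding.

**Cross-correlation.** Pearson coefficients of the overlapping segments at
every integer-sample lag within ±0.5 s (per-lag normalisation, so values
stay in [−1, 1] even for short windows); the reported extremum is the
largest |coefficient|, sign preserved, positive lag meaning the second
series lags the first. The pipeline correlates pitch acceleration vs α,
pitch acceleration vs θ, and θ vs β over the window from nose-down onset
through pitch settling; including the pre-switch parachute stretch would
dilute the transition signal.

## The simulator

State `(x, z, v_x, v_z, β, β̇)`, integrated with adaptive high-order
Runge–Kutta (DOP853, rtol 1e-8, atol 1e-10), each posture phase integrated
separately with event detection for the switch and for the floor so
discontinuities are never smeared.

Translation: `a = g + (q/m)(C_D(α) n_D + C_L(α) n_L)` with
`q = ½ρ|v|²A`. Coefficient curves are the standard blunt-body/flat-plate
shapes `C_D = C_D0 + C_D1 sin²α`, `C_L = C_L1 sinα cosα` — no measured
coefficient curves exist for this system, and these shapes reproduce the
two observed regimes (high-AoA drag-dominated parachuting; mid-AoA
higher-lift gliding). `lift_scale = 0` degenerates to the drag-only
reference cylinder, which also has the closed form
`v(t) = v_t tanh(gt/v_t + atanh(v0/v_t))`, `v_t = √(2mg/(ρC_D A))`, used as
an independent oracle for the integrator (agreement to 1e-6).

Pitch: `I β̈ = q A L C_M(α) − c β̇` with `C_M = −k_m(α − α_trim)` for the
active posture — both postures statically stable, trim AoA 88° while
parachuting and 67.8° while gliding. The moment reference length is the
body length L; inertia defaults to the uniform-rod value mL²/12. `k_m` and
`c` are tuned by linearising about the gliding trim so that the pitch mode
has a chosen natural frequency and damping ratio (defaults 4.7 Hz and 0.23,
the observed young-nymph means).

The standard trial (`default_sim_config`) solves the coefficient magnitudes
so that the analytic steady glide matches the observed young-nymph landing
state: tan θ\* = C_D/C_L at the gliding trim with θ\* = 70.8°, and
`½ρu\*²A√(C_D²+C_L²) = mg` with u\* = 237.6 cm/s (m = 22.7 mg,
A = 66.1 mm², ρ = 1.204 kg/m³). The gliding trim of 67.8° makes the
equilibrium pitch θ\* − α_trim = −3.0°, the observed near-horizontal
gliding posture. `C_D0 = 0.4` keeps the drag curve flat between the two
trims so the parachuting terminal descent speed slightly exceeds the
gliding one — that ordering is what produces the characteristic profile of
a descent-speed maximum at the transition followed by vertical
deceleration.

**Posture switch.** `SimConfig` defaults to an instantaneous trim change.
The standard trial instead ramps the trim linearly over 0.16 s (the
observed nose-down interval) and triggers at 99% of the analytic
parachuting terminal speed. Both choices are deliberate: an instantaneous
switch drops drag before lift has built, producing a descent-speed
overshoot that relocates the 95%-of-maximum landmark *after* the switch and
erases the parachuting phase; the finite posture change (the legs sweep
over a finite time) keeps the overshoot small so terminal speed is attained
during parachuting, a clear interval before glide initiation — the ordering
the real trajectories show.

Landmark placement: head = CoM + (L/2)(cos β, sin β), abdomen mirrored, so
the midpoint CoM is recovered exactly. Tracking noise is i.i.d. Gaussian
per landmark coordinate (default σ 0.3 cm, the scale of a fraction of a
pixel at a few pixels per cm), seeded and recorded in trial metadata.

**Cohort generator.** Age templates interpolate the first-instar endpoints
(mass 22.7 → 66.2 mg, planform area 66.1 → 72.1 mm², length 20 → 24 mm);
individuals jitter mass and area by 5% (multiplicative, log-normal). One
shared aerodynamic model is used for the whole cohort — the body shape
changes little over the instar — so wing loading alone drives terminal
speed and landmark timing; pitch parameters are re-tuned per individual.
Trials end at a floor 450 cm below release or at 2.5 s, whichever comes
first. The floor matters scientifically: with a fixed drop height, heavier
individuals burn more height before gliding and convert less of their
descent into horizontal travel, which is exactly the mechanism behind the
ontogenetic decline of the glide index; the heaviest group parachutes into
the floor without ever initiating a glide, reproducing the observed
behaviour of late-instar trials. A lower floor (≤ 3.5 m) truncates the
heaviest group before terminal-speed attainment and breaks the cross-group
landmark ordering.

## Glide-performance geometry

Glide index GI = d/(h₀ + h_g) from the horizontal distance to target d,
pre-glide height loss h₀ and gliding height loss h_g. The sub-canopy reach
constraint is implemented as d_max = (h_max − h₀)·cot θ with θ measured
from the horizontal: a steeper glide reaches less and the reach vanishes in
the vertical-fall limit, consistent with the geometry of the configuration.
The literal tan-form (appropriate if θ were measured from the vertical) is
available behind a flag (`literal_tan=True`) for comparability.

Allometry is ordinary least squares on log10–log10 axes, returning the
exponent with its standard error and R²; the regressor/response pairing is
caller-chosen rather than hard-wired. LOESS aggregation pools all trials'
points and fits tricube-weighted local linear regressions
(`statsmodels.lowess`) at a common grid, with pointwise s.e.m. from the
between-trial spread.

## What the synthetic data do and do not show

The simulator emulates: the accelerating fall, terminal-speed attainment,
the nose-down transition with an underdamped pitch ring-down, convergence
to a steep equilibrium glide, digitisation noise, ontogenetic wing-loading
scaling, and floor-truncated trials. It does not model: 3D righting and
yaw steering (only their height/time arithmetic is computed), leg
articulation and its effect on the coefficient curves (postures differ only
in trim), unsteady aerodynamics (added mass, vortex shedding), wind, or
sensory control. Passing recovery tests on synthetic data therefore
demonstrates that the estimators are correct for trajectories governed by
quasi-steady two-posture dynamics at these Reynolds numbers (~3×10³), not
that real insect aerodynamics are fully captured.

## Numerical details and degenerate inputs

- Glide angle is null where speed < 1e-6 cm/s (direction undefined); the
  decomposition is null below 1e-6 m/s.
- Zero initial speed is an integration error (drag direction undefined);
  non-finite states abort with the time stamp.
- Landmark ties break to the earliest sample; all missing landmarks are
  explicit nulls in JSON output, never omitted keys.
- Result files store 17 significant digits and re-read with round-trip
  float parsing, so every writer/reader pair is lossless at double
  precision; reruns with equal seeds are byte-identical.
- Problem sizes used by the verification scripts — 2.5 s trials at 50 Hz
  (126 samples), 100-replicate estimator ensembles, cohorts of 3–5 trials
  per age group — were chosen as the smallest sizes at which the group
  orderings and estimator distributions are stable.

## Known limitations

- The damping-ratio estimator assumes the ring-down dominates its window;
  overlapping manoeuvres or baseline drifts faster than the oscillation
  period bias it (real damping-ratio estimates scatter widely for the same
  reason).
- The FFT frequency of a strongly damped, short ring-down has an intrinsic
  ±0.1–0.2 Hz scatter under realistic noise (see above).
- C_L/C_D cannot be estimated from real trials without air-density and
  reference-area assumptions; dimensionless coefficients are available only
  for simulated trials where the truth is known.
- The two-posture pitch model is linear in α about each trim; large
  excursions couple nonlinearly with translation, which is visible as
  asymmetric swing sequences in simulated ring-downs.
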