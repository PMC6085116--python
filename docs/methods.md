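# Methods

This note documents the models, defaults, and numerical choices behind
`wristsim`, and what the synthetic experiment can and cannot say about
physical wrist simulators.

## Scope and coordinates

The wrist is modelled as two controlled rotational degrees of freedom:
flexion–extension (FE, flexion positive) and radioulnar deviation (RUD,
radial deviation positive). Six muscles act across it: FCR, FCU, ECRL,
ECRB, ECU, APL. Everything distal (thumb carpometacarpal kinematics, the
APL's multiple distal tendon slips, extrinsic finger/thumb muscles) is out
of scope; the APL's slip-to-slip variability is represented only as
inter-specimen moment-arm variance. Units are fixed package-wide: forces N,
lengths mm, torques N·mm, inertia kg·mm², angles stored in degrees and
converted to radians wherever a moment arm or a sine is evaluated.

## Synthetic specimens

Each specimen carries one `MuscleSpec` per muscle: PCSA (cm²), specific
tension (N/cm²), minimum-activity fraction, and one moment-arm polynomial
per axis (mm, as a function of the same-axis angle in radians; degree 0 by
default). Force bounds are

* F_max = PCSA × specific tension,
* F_min = minimum activity × F_max,

modelling the maximal isometric force and the minimal tone kept on each
cable. Defaults: specific tension 35 N/cm², minimum activity 0.025, PCSA
(cm²) FCR 2.0, FCU 3.4, ECRL 2.4, ECRB 2.9, ECU 3.4, APL 1.9, and neutral
moment arms (mm, (FE, RUD)) FCR (10, 4), FCU (12, −14), ECRL (−7, 13),
ECRB (−12, 6), ECU (−6, −17), APL (4, 19). These are literature-scale
placeholder values — no individual anatomical measurements stand behind
them — chosen to realize the qualitative role table: APL a weak flexor and
the strongest radial deviator per unit force; FCR/ECRL its synergists; ECU
its antagonist about both axes; FCU/ECRB mixed. They are configuration
entries, not constants.

Inter-specimen variability is log-normal multiplicative noise (unit mean,
CV 0.15 by default) applied independently to each PCSA and each moment-arm
magnitude; signs are taken from the means, so the role table holds for
every specimen at every seed by construction rather than by rejection
sampling. Each specimen draws from its own child stream of the cohort base
seed (`numpy` `SeedSequence.spawn`), so enlarging a cohort never changes
earlier specimens. Default cohort size is 7.

The hand segment is a point mass on a massless link: mass 0.45 kg, centre
of mass 60 mm from the wrist axes, principal inertias 1620 kg·mm²
(≈ m·d²) about both axes, viscous damping 5 N·mm·s/rad per axis — a
plausible adult hand, kept deliberately simple because muscle-force
distribution, not inertial dynamics, is the object of study.

## Tendon-excursion moment arms

The moment arm about an axis equals the derivative of tendon excursion
with respect to the joint angle. The synthetic passive trial integrates the
specimen's true moment-arm polynomial over an angle grid (FE −35…55°,
RUD −20…20°, 25 points by default), anchors excursion to zero at the first
angle, and adds i.i.d. Gaussian noise (default σ = 0.1 mm, a realistic
displacement-transducer scale). The estimator least-squares-fits the
excursion with a degree-2 polynomial (so the moment arm is affine in the
angle) and differentiates analytically; the fit RMSE is reported on the
excursion residuals. With 50 points over ±0.5 rad and σ = 0.1 mm, the
slope-error sd of a linear fit is σ/√Σ(θ−θ̄)² ≈ 0.05 mm, which is why the
recovery tests bound the mean absolute error at 0.2 mm with a wide margin.
The pipeline defaults to "estimated" mode (the controller consumes these
fits, mirroring the physical workflow); "oracle" mode with true moment
arms is a configuration switch used in tests.

## Trajectories

Four cyclic motions, specified by their waypoints, are parameterized as
smooth sinusoids/ellipses (period 4 s per cycle by default; only waypoints,
not speed or waveform, are prescribed by the protocol, and smoothness keeps
torque demands continuous):

* FE-5030: θ_FE(t) = 10 + 40·cos(2πt/T), θ_RUD = 0 (50° flexion to 30°
  extension);
* RUD-15: θ_RUD(t) = −15·cos(2πt/T) (15° ulnar to 15° radial);
* circumduction: (θ_FE, θ_RUD) = (30·cos φ, ∓10·sin φ), the minus sign
  giving the clockwise order flexion → ulnar → extension → radial and the
  plus sign its mirror.

The per-cycle sample count is rounded to a multiple of four so the phase
hits 0, π/2, π, 3π/2 exactly: every extremum is sampled and each cycle
closes on its start to machine precision. Five cycles per motion by
default; the first is discarded from all statistics as a transient (a
pipeline convention recorded in run metadata).

## Force distribution

The redundancy resolver minimizes the normalized effort Σ(fᵢ/F_max,ᵢ)²
subject to torque balance and bounds. The criterion for the physical rig's
controller is not public; normalized effort is the standard
static-optimization choice, strictly convex (unique solution, hence
bitwise-reproducible and oracle-testable), and a summed cubed-stress
criterion Σ(fᵢ/PCSAᵢ)³ is provided so any conclusion can be checked for
criterion-robustness. All headline properties hold under both.

Numerically, the solver maximizes the 2-D dual: f(λ) = clip(h(Rᵀλ)) with h
the inverse marginal cost, and a damped semismooth Newton iteration drives
the torque residual below 1e-9·max(1, |τ|). Warm starts from the previous
control step make the per-step cost one or two Newton iterations. If
Newton stalls, the instance is re-checked by bounded least squares: a
demand whose closest achievable torque is farther than 1e-6·max(1, |τ|)
raises an infeasibility error carrying that closest torque (the controller
falls back to it and counts the step); otherwise an SLSQP polish finishes
the rare hard instance. The achievable torque set itself is computed
exactly as a zonotope (Minkowski sum of the muscles' torque segments) for
diagnostics and cross-validation.

Lower bounds are hard constraints. This matters scientifically: an ablated
muscle loses not only its optimized force but also its minimum tone, and
that tone's torque is what the antagonist was partly working against — the
mechanism behind the antagonist unloading seen in the results. Note that
with strictly positive lower bounds the intact and ablated feasible sets
are not nested (ablation removes a muscle's column *and* its minimum-tone
constraint), so "removing a muscle cannot lower the optimal cost" is
guaranteed — and tested — in the slack-lower-bound regime f_min = 0.

## Control loop

Per step (dt = 4.5 ms, inside the 4–5 ms real-time iteration range):
torque demand = PD on the target posture and velocity + exact gravity
compensation; the resolver distributes it over non-ablated muscles; the
plant integrates I·θ̈ = Σrᵢfᵢ + τ_g − b·θ̇ with semi-implicit Euler.
Gravity for the vertically upward hand is τ_g = −m·g·d·sin θ per axis
(odd, zero at neutral, axes treated independently). Gains default to
critical damping at 3 Hz per axis by pole placement against the specimen's
inertia and damping; with the 0.25 Hz motions this keeps steady-state RMS
tracking error around 0.2–0.5° (hard failure at 20° raises a divergence
error naming the gains). Quasi-static mode bypasses the dynamics: posture
snaps to the target and the demand is the reference inverse-dynamics
torque I·θ̈_ref + b·θ̇_ref − τ_g; it agrees with a stiff dynamic run to
within 5% on grid forces and is useful for fast sensitivity sweeps.

Ablation removes the muscle's column from every distribution problem, so
its recorded force is exactly 0.0 at every step — the software equivalent
of slackening and switching off its actuator.

## Statistics

Forces are evaluated at every 10° in FE and every 5° in RUD by averaging
all steady-state samples within a ±1° phase window around each grid angle
(circumduction FE values are kept separate per traversal limb, tagged by
the sign of θ̇_FE); peaks are the mean over steady-state cycles of the
within-cycle maximum. Whether a physical experiment averages passes before
testing is a protocol detail not fixed by the published description;
averaging over steady-state passes is this pipeline's declared convention.

The paired test is the two-sided Wilcoxon signed-rank test with W =
min(W⁺, W⁻), zeros dropped (Pratt handling by flag), mid-ranks for ties.
The exact p doubles the null CDF of W⁺ computed by convolution over the
observed ranks — identical to enumerating all 2ⁿ sign assignments, which
the test suite does independently. The asymptotic p uses z =
(W − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48) with no continuity
correction; at n = 7 without ties this yields the characteristic p-values
0.018, 0.028, 0.043, 0.063 for W = 0–3, which is why the asymptotic value
is the default reported p (the exact p is always computed alongside). The
percent change reported per muscle is the mean over specimens of
100·(peak_ablated − peak_intact)/peak_intact. No multiple-comparison
adjustment is applied, and the pipeline is unconditionally nonparametric —
a normality-check hook exists for exploration but never gates the test.

## What the synthetic study does and does not show

Passing tests demonstrate that *given* a six-muscle wrist with the stated
role structure, minimum muscle tone, and effort-minimizing force
distribution, switching off the APL necessarily shifts load onto FCR and
ECRL and unloads ECU — robustly across specimens, motions, moment-arm
estimation noise, and both effort criteria. The synthetic cohort does not
reproduce any real specimen's numbers: anatomical parameters are
placeholder-scale, the plant omits inter-axis coupling, tendon elasticity,
force–length/velocity properties, actuator slew and load-cell noise, and
the real rig's proprietary control law. Percent changes printed by this
package are therefore comparable to physical experiments in sign and
rough order of magnitude, not in value.

## Problem sizes

Default study: 7 specimens × 4 motions × 2 conditions × 5 cycles at
~889 steps/cycle ≈ 250k solver calls, about 40 s on one CPU. The test
suite's end-to-end checks run this default study once per effort
criterion; solver-oracle and statistics cross-validations use hundreds of
randomized small instances.
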