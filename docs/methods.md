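# Methods

This note documents the model, the controllers, the cost function, the
optimization protocol, the analysis chain and the synthetic-trace generator
implemented in `stsreflex`, together with the numerical choices and the
design decisions taken where the underlying description left the design open.

## Musculoskeletal model

The body is a sagittal-plane linkage of seven rigid segments — a single
lumped torso+pelvis+head segment (arm mass folded in), and thigh, shank and
foot per side — with 9 degrees of freedom: anteroposterior translation,
vertical translation and pitch of the root segment, plus pin joints at hips,
knees and ankles. Segment lengths, masses, centre-of-mass positions and radii
of gyration are scaled from total height (default 1.80 m) and mass (default
80 kg) with Winter's anthropometric coefficients; the lumped torso receives
the mass remainder so the segment masses always sum to the configured total.

Generalized coordinates are `[x_hip, y_hip, phi_torso, hip_L, knee_L,
ankle_L, hip_R, knee_R, ankle_R]`. All joint angles are zero in upright
stance and increase with flexion (hip: torso pitching forward relative to the
thigh; knee: shank folding; ankle: dorsiflexion).

**Reported hip angle.** The controller thresholds, cost rules and analysis
chain all act on the *torso pitch with respect to vertical*, reported as "the
hip angle". With the pelvis lumped into the torso segment there is no lumbar
joint, and the seated hip value of 12 deg encodes the average seated torso
inclination; a threshold sequence of 12 deg (seated) -> above 77 deg
(lift-off) -> at or below 0 deg (upright) is only self-consistent for a
signal that is zero in stance and equals the seated inclination at start —
i.e. the torso pitch. The anatomical hip joint coordinate still exists (its
seated value, about 68 deg, follows from the seated pose) and is actuated by
the hip muscles; only the *reported/controlled* hip signal is the torso
pitch.

**Seated pose.** The configured initial angles (hip 12, knee 85, ankle
61 deg) are interpreted as: torso pitch 12 deg; anatomical knee flexion
85 deg; anatomical ankle dorsiflexion 61 deg with the foot initially pitched
toes-up (about -32 deg) so that the shank stands at a realistic seated
inclination (29 deg from vertical). The *placed* pose hovers: the pelvis
contact sphere starts 3.5 cm above the seat plane and the heel spheres about
4 cm above the ground (both published placements, mutually consistent only
for a hovering pose). Rollouts start from the *static sitting equilibrium*
obtained by settling the placed pose under gravity with the joint angles and
pitch held (root translation free) and zeroing velocities: the seat then
carries roughly 70 % of body weight and the heels the rest, and the lift-off
event (seat force reaching 0 N) is well defined. The early toe drop and
transient toe lift mirror the behaviour expected of the original simulation
scenario.

**Contact.** Five spheres (toes, calcanei: radius 4 cm, against the ground
plane; one pelvis sphere against the finite-length seat plane) produce
Hunt–Crossley normal forces `k d^1.5 (1 + 1.5 c ddot)` (k = 1e6 N/m^1.5,
c = 1 s/m) and regularized Coulomb friction `-mu F_n tanh(v_slip/0.01)`
(mu = 0.9), which keeps |tangential| <= mu * normal for every slip velocity.
The tangential force acts at the sphere's lowest point (its torque about the
sphere centre is included); the slip velocity is that of the material point.

**Passive joint structures.** Each joint carries viscous damping
(1 N m s/rad) and soft range-of-motion stops (200 N m/rad, engaged outside
hip [-30, 150], knee [-15, 140], ankle [-40, 90] deg). These stand in for
the ligaments and soft tissue that keep a real (and a high-fidelity
simulated) skeleton inside physiological ranges, and they bound the system's
stiffness so the fixed-step integrator remains stable when a segment is
briefly unloaded.

**Integration.** Fixed-step semi-implicit Euler with a velocity-midpoint
position update (kick, then drift with `(v_n + v_{n+1})/2`), dt = 1 ms.
The position update is second-order: free fall reproduces `g t^2 / 2` to
machine precision and a one-leg compound pendulum matches its linearized
frequency within 2 %. With contacts and actuation disabled, mechanical
energy drifts by less than 0.1 % per simulated second. The mass matrix and
bias forces are assembled analytically (every attached point is a closed-form
sum of sines/cosines of body orientations, which are linear in q).

**Symmetric rollouts.** The controllers are symmetric by construction (one
stimulation drives both sides), so the full rollout integrates the dynamics
projected onto the left/right-symmetric subspace (a 6x6 solve). This keeps
the two sides bitwise identical — floating-point pivoting noise would
otherwise be amplified by contact events — and halves the solve cost. The
general 9-DOF path (used by `step_dynamics`) places no symmetry constraint.

## Muscle channels

Nine symmetric Hill-type channels per side (GLU, ILPSO, RF, VAS, HAMS, BFSH,
GAS, SOL, TA) act through constant, posture-averaged moment arms; the
channel table is CSV-configurable so the set can be extended. Tendons are
rigid. Normalized fiber length is `L = 1 + sum_j r_j theta_j / s` with an
effective excursion scale `s` (0.2–0.25 m) which absorbs tendon compliance
and moment-arm variation; extensors stretch as joints flex, and L stays in
a physiological band (about 0.8–1.45) over the STS range.

Force: `F = F_max (a f_L(L) f_V(v) + f_P(L))` with a Gaussian force–length
curve (width 0.45), a Hill force–velocity curve (zero force at the maximal
shortening rate of 10 s^-1, eccentric plateau 1.8), and a quadratic passive
element engaging beyond a slack length of 1.2 — seated postures (L about
1.25) are nearly passive-force-free, as in physiological parallel-elastic
curves; extreme stretches are bounded by the joint stops rather than the
muscle curve. Activation follows first-order excitation–activation coupling
(tau_act 15 ms, tau_deact 50 ms, exact exponential step) with a floor of
a_min = 0.01; figure-style outputs can renormalize to the display convention
[0.1, 1].

With torso and pelvis lumped into one rigid body, a torso-extensor channel
would span no joint; it is therefore omitted from the default set.

## Reflex controllers

Stimulation of channel m in phase n:

    A_m = A0_{m,n} + sum_s k_{s,m,n} (x_s - x_ref,n) + k_l,m (L_m - L0_m)

clamped to [a_min, 1] after summation. Routed signals per phase: flexion
momentum (both controllers): torso pitch, pitch rate, pitch acceleration;
momentum transfer and extension (4-phase) and the merged phase (2-phase):
torso-CoM position, velocity and acceleration in x and y; stabilization
(4-phase): torso-CoM and pelvis position, velocity and acceleration in x.
Position-type signals carry one optimizable reference per signal per phase.
Length-reflex gains and offsets are shared across phases. In flexion
momentum only RF receives vestibular terms (the model has no rectus
abdominis; iliacus/psoas vestibular reflexes are disabled there as their
inclusion prevents convergence); every channel keeps its tonic and length
terms in every phase. Acceleration feedback channels are first-order
low-pass filtered at 20 Hz before entering the controller; raw
penalty-contact accelerations are unusable.

The phase machines are non-returning, advancing at most one phase per step:
1 -> 2 when hip > 77 deg; (4-phase) 2 -> 3 when the torso CoM passes the
calcaneus landmark with non-positive forward velocity and shank inclination
below 90 deg from the +x axis; 3 -> 4 when knee <= 5 deg and hip <= 0 deg.
The 2-phase controller merges everything beyond the first transition.

**Parameter layout.** The flat optimization vector is: `k_l` per channel;
`L0` per channel; then per phase: tonic per channel, position reference(s),
vestibular gains (phase 1: RF's three; later phases: six per channel,
channel-major). For C channels this gives `24 C + 10` parameters (4-phase)
and `10 C + 6` (2-phase): 226 and 96 at the default C = 9. Per-class bounds
(tonic [0.01, 1], gains by signal type, references in rad/m) are
config-exposed; the count formula is tested by enumeration.

## Cost function

Every rule is a penalized predicate over the body feedback; a violated
predicate contributes `weight * min(excess, cap)^2 * dt` per step, with
excess the distance past the published threshold and cap = 2 (in the
signal's own units). The quadratic measure gives the evolutionary search a
graded signal; the saturation keeps millisecond contact transients from
dominating whole-rollout integrals. There is no effort or energy term.

4-phase rules follow the phase-wise table (suboptimal forward acceleration
below 1.2 m/s^2 in flexion momentum; pelvis/torso backwards movement, hip
below -11 deg, knee overextension, talus/toe lift thresholds 0.1/0.15/0.2/
0.3 m/s, torso falling `p_torso,y < p_pelvis,y`, stance hip band +/-8 deg).
The 2-phase merged phase applies hip-angle-conditioned groups: backwards
movement only while hip > 44 deg; extension-progress requirements while
8 < hip < 77 deg; the stance band and knee <= 11 deg once hip <= 8 deg; and
unconditional falling / knee-overextension (-15 deg) / feet rules.

Two published rows required fixing a reading (both documented here because
the source is ambiguous):

* the extension-phase "torso over toes" comparison is implemented on the
  anteroposterior axis (`p_torso,x > p_toes,x`, the torso overshooting the
  base of support), matching the stabilization-phase bad-posture rule;
* the merged-phase velocity rows are implemented as *progress requirements*
  — penalize when hip extension is slower than 10 deg/s, or when the knee
  is flexing — since under the angle convention (angles grow with extension
  in the source; flexion-positive here) the alternative literal reading
  would penalize the desired movement and make quiet sitting free, which
  contradicts the stated purpose of driving the extension subtask.

Early termination (fall: hip point below 0.25 m or |pitch| > 2 rad;
numerical divergence) adds `k_fall * (horizon - t_end)` with k_fall =
50 s^-1 against the 20 s reference horizon. Default rule weights are 1
except: suboptimal acceleration x10, merged-phase hip progress x50, knee
progress x10. These defaults (weights are not published) shape the search
ordering — completing the task < lingering anywhere < falling — while each
rule's capped rate stays below the fall-penalty rate, so "failing fast"
never beats surviving.

## Optimization

CMA-ES (standard (mu/mu_w, lambda) with rank-1 + rank-mu covariance updates
and cumulative step-size adaptation) is implemented in-package and validated
on sphere/Rosenbrock benchmarks (20-D sphere below 1e-8; 5-D Rosenbrock
below 1e-4; bit-reproducible per seed). The search operates in box-normalized
coordinates (each parameter mapped to [0, 1] from its class bounds) with
sigma0 = 0.2 by default; candidates are evaluated after projection onto the
box, with a small quadratic out-of-box penalty added for selection. The
protocol runs independent seeded searches (default 10 runs, generation cap
10000 — the published iteration cap is read as generations, with an optional
evaluation cap exposed as well — horizon 20 s). Objective evaluations are
deterministic given the vector, so parallel evaluation within a generation
is order-independent.

The sequential-phase structure exposes the search to genetic drift
(late-phase parameters update randomly until earlier phases succeed); no
remedy beyond the auxiliary transition conditions and an optional stagnation
restart is applied.

## Analysis chain

Kinematic phase ends on simulated traces: lift-off at the first sample where
the seat force reaches 0 N (armed only after the seat has been loaded, since
the model starts just above the seat); momentum-transfer end at the minimum
shank inclination w.r.t. the +x axis; extension end at the first downward
crossing of |hip extension acceleration| below 0.0065 deg/s^2 after
momentum transfer; stabilization end at the 0.0015 deg/s^2 crossing. The
crossing detector uses the *magnitude* of the acceleration with arming and a
3-sample sustain requirement: during movement the signed acceleration passes
through zero at every inflection, so a signed test would fire mid-movement,
and even the magnitude can graze a tiny threshold for a single sample when
the sampling grid happens to land on an inflection; requiring the magnitude
to stay below threshold for a few consecutive samples isolates the intended
event — the joint becoming still. Experimental-style traces
use the seat-force first-derivative minimum, maximum dorsiflexion, and the
0.0065 deg/s crossing of extension *velocity*; stabilization detection is
not applied. Derivatives are central differences; an optional zero-phase
Butterworth pre-filter is available (off by default — at these thresholds
filter transients, not noise, are the limiting factor on clean traces).

Success: all phases in order, extension no longer than 1 s, and standing
(stabilization end to trace end) at least 3 s. Cycles are linearly resampled
to 100 points between start and extension end; boundary times are re-expressed
in cycle percent. Cross-correlation is the maximum Pearson coefficient over
integer lags within +/-50 % of the cycle (ties to the smallest |lag|,
zero-variance channels yield NaN rather than a silent 0); a channel pair
matches when r exceeds 0.7 strictly. Run aggregation is the pointwise mean
+/- std with phase-percentage statistics.

## Synthetic traces

`generate_sts_trace` builds surrogate reference recordings (the experimental
data are not deposited): minimum-jerk joint excursions from the seated pose
to upright, a seat force decaying to exactly 0 N at the planted lift-off
instant with the ground force complementing to body weight, a shank
inclination dipping to its minimum exactly at the planted momentum-transfer
instant, Gaussian activation bursts at plausible cycle positions, optional
seeded per-channel noise, and — after the cycle — a slow exponential
hip-extension creep whose initial acceleration (amp/tau^2 with defaults
0.0012 deg / 0.5 s) lies between the extension and stabilization detection
thresholds. That creep is what separates the extension-end and
stabilization-end events on a simulated-style trace, mirroring the "hips
keep extending slightly while standing" behaviour the detectors were
designed around. Default sampling is 250 Hz (the acquisition rate of the
instrumented-chair protocol the traces emulate).

What the generator does *not* emulate: marker/EMG measurement noise spectra,
stand-to-sit segments of repeated-cycle tests, inter-subject variability
beyond the user-set targets, or any coupling between channels. Passing
round-trip tests on these traces therefore validates the measurement chain's
logic, not its robustness to real recording artefacts; the detection
thresholds (0.0065 / 0.0015 deg/s^2) are so small that channel noise above
roughly 1e-4 deg would mask the extension/stabilization events entirely.

## Reference controller and scaled-down study

The packaged demo parameter set (`stsreflex/data/demo_2phase.json`) is a
2-phase controller obtained with this package's own protocol at desk scale —
hand-initialized reflex gains refined by seeded CMA-ES runs at a 12 s
horizon — and frozen for reproducible demonstrations and tests. The
acceptance script re-simulates it from scratch and re-derives its phase
percentages; nothing about the trajectory is stored. The full published
protocol (10 runs x 10000 generations x 20 s) is hours of single-core
compute and is available through `ReflexSTS.fit` / the CLI unchanged.

## Known limitations

* Constant moment arms and rigid tendons: joint-angle-dependent leverage is
  folded into excursion scales; muscle-level force validation is out of scope.
* The reduced 9-channel set cannot reproduce per-muscle activation detail of
  a 50-actuator model (e.g. separate vastus heads).
* The lumped torso makes "hip angle" a torso-pitch surrogate; anatomical hip
  trajectories are not comparable to goniometric data.
* Penalty contact plus a 1 ms fixed step produce small force oscillations on
  the seat sphere; the analysis reads lift-off from the exact 0 N condition,
  which is robust to this.
* The cost weights, violation cap and fall penalty are this package's
  design choices (the source publishes predicates only); results that depend
  on the weighting (e.g. which local optimum a short search finds) should be
  interpreted accordingly.
* Post-stance quieting is slower than in the high-fidelity engine this model
  reduces: optimized controllers reach lift-off on a human-like schedule
  (~0.5 s) but need 2-4 s, not ~1 s, for the hip acceleration to fall below
  the tiny extension/stabilization thresholds. Because the STS cycle is
  normalized to the extension end, that stretches the denominator and pushes
  the early phase-end percentages well below instrumented-STS proportions;
  comparisons of cycle percentages against published values should expect
  this systematic compression. Desk-scale gain searches (hundreds to a few
  thousand generations on one core) also explore far less than the original
  protocol, so the packaged controller is one successful style, not a
  population statistic.
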