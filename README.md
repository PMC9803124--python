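# stsreflex

Reflex-based predictive simulation of sit-to-stand (STS).

Standing up from a chair is one of the most demanding activities of daily
living, and how the nervous system coordinates it is not directly
measurable. `stsreflex` asks whether a small set of *reflexes* — linear
feedback pathways from vestibular-style torso kinematics and muscle length
onto individual muscles — is sufficient to drive a musculoskeletal model
from a seated pose to stable standing. It is aimed at researchers in
computational neuromechanics and motor control who want a self-contained,
fast, fully scriptable sandbox for reflex-controller hypotheses on the STS
task.

## What is inside

* **Planar musculoskeletal model** — a sagittal 7-segment, 9-DOF linkage
  (lumped torso+pelvis+head, thighs, shanks, feet) scaled from total height
  and mass, seated on a 0.45 m chair, with Hunt–Crossley sphere contact at
  the toes, heels and pelvis, starting from the seated pose (hip 12°, knee
  85°, ankle 61°).
* **Hill-type muscle channels** — nine symmetric muscle groups (GLU, ILPSO,
  RF, VAS, HAMS, BFSH, GAS, SOL, TA) with force–length/velocity curves,
  passive elasticity and first-order activation dynamics.
* **Phase-dependent reflex controllers.** The stimulation of muscle m in
  phase n is

      A_m = A0_{m,n} + Σ_s k_{s,m,n} (x_s − x̄_s,n) + k_l,m (L_m − L0_m),

  clamped to [0.01, 1], where the routed signals x_s are the torso pitch
  θ, θ̇, θ̈ during *flexion momentum* and torso-CoM (plus pelvis, in
  stabilization) position/velocity/acceleration afterwards. Two variants: a
  **4-phase** controller with separate gain sets per kinematic phase
  (flexion momentum → momentum transfer → extension → stabilization,
  226 parameters) and a **2-phase** controller that merges everything after
  lift-off (96 parameters). Phase transitions are non-returning (e.g.
  hip > 77° ends flexion momentum).
* **Phase-dependent cost function** for controller optimization: penalized
  predicates per phase (suboptimal forward acceleration, backwards motion,
  joint overextension, feet lift/slide, falling) plus an early-termination
  penalty. No energy term.
* **CMA-ES** (implemented in-package) with the independent-runs protocol:
  `fit(runs=10, max_generations=10000, horizon=20.0)`.
* **Analysis chain** — kinematic phase detection (seat force reaching 0 N;
  minimum shank inclination; hip extension acceleration thresholds
  0.0065 / 0.0015 °/s²), STS success rules (extension ≤ 1 s, standing
  ≥ 3 s), 100-point cycle normalization, lagged cross-correlation
  (match at r > 0.7), and across-run aggregation.
* **Synthetic trace generator** standing in for non-deposited experimental
  recordings, with user-set phase targets and seeded noise.

## Worked example

```python
import stsreflex as sr

sts = sr.ReflexSTS(controller_type="2phase")   # 1.80 m / 80 kg model
params = sr.sts.load_demo_params()             # packaged reference gains

res = sts.simulate(params, horizon=20.0)       # deterministic rollout
traj = res.trajectory()
b = sr.detect_phases(traj)
ok, reasons = sr.check_success(b, horizon=res.t_end)
cycle = sr.normalize_cycle(traj, b)
print(res.termination, ok)
print({k: round(v, 2) for k, v in cycle.boundaries_pct.items()})
```

prints

```
completed True
{'liftoff': 13.26, 'momentum_transfer': 76.66, 'extension': 100.0}
```

i.e. the reflex controller stands the model up and keeps it standing for the
rest of the run: the buttocks leave the seat 0.5 s in (13.3 % of the STS
cycle), the shank-inclination minimum that ends momentum transfer comes at
76.7 %, and the run is classified successful (extension under 1 s, standing
over 3 s). Relative to instrumented human STS the simulated rise spends less
of its cycle before seat-off — the model quiets down more slowly after
standing, which stretches the normalized cycle (see `docs/methods.md`,
Known limitations). To optimize a controller from scratch instead of using
the packaged gains:

```python
results = sts.fit(runs=10, max_generations=2000, seed=0, horizon=12.0)
print(results.summary())        # per-run costs, success flags, phase %
```

(Expect hours of CPU time at that budget; the library is also exposed on
the command line as `stsreflex optimize | simulate | fixtures | analyze`.)

## Layout

| module | contents |
|---|---|
| `stsreflex.config` | anthropometry, chair/contact geometry, integration constants |
| `stsreflex.model` | planar dynamics, seated-pose construction, contact forces |
| `stsreflex.muscles` | Hill-type channels, activation dynamics, torque mapping |
| `stsreflex.control` | reflex law, signal routing, phase machines, parameter codec |
| `stsreflex.cost` | phase-dependent penalty rules and cost reports |
| `stsreflex.cmaes` / `stsreflex.optimize` | CMA-ES and the independent-runs protocol |
| `stsreflex.simulate` | the compiled closed-loop rollout |
| `stsreflex.analysis` | phase detection, success rules, cycle normalization, cross-correlation |
| `stsreflex.fixtures` | synthetic STS trace generator |
| `stsreflex.sts` | `ReflexSTS` model object and fit results |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
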