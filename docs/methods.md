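# Methods

## Model

The system is one spatial degree of freedom: a muscle with a fixed origin,
an in-series Hookean tendon, and a point load resting on the ground
directly below. Geometric closure ties the states together — muscle
shortening equals load rise plus tendon elongation change — so the muscle's
shortening velocity is `V_m = v_load + de/dt`. The tendon is massless and
purely elastic (no viscoelasticity, no toe region); it cannot push, and
slack is represented by zero force. The load is a gravitational point mass
that cannot fall below its resting position; an optional catch pins it for
a fixed delay after stimulation onset. Muscle mass and tendon inertia are
ignored in the dynamics; joint geometry and mechanical advantage are out of
scope.

Muscle force is `P0·[a(t)·f_L·f_V] + P0·f_P`:

* **Active force–length** `f_L`: cubic regression over percent of optimal
  length, used raw as a scaling factor (it evaluates to 1.05 at 100% L0 and
  crosses zero near 59.2% and 148% L0). An optional normalize-to-peak
  switch divides by the cubic's interior maximum; it is off by default.
  Simulation stops if the muscle shortens past the zero crossing.
* **Passive force–length** `f_P`: cubic regression, clamped to zero below
  100% L0 and floored at zero elsewhere. It is added to the active term,
  is not scaled by activation or velocity, and is transmitted through the
  tendon. Note it is discontinuous at exactly 100% L0 (0 below, 0.05 at).
* **Force–velocity** `f_V`: the normalized Hill hyperbola solved for force,
  `b(1+a)/(V+b) − a`, with `a = 0.52`, `b = 4.17` lengths/s, hence an
  implied unloaded velocity `b/a = 8.02` lengths/s. Velocities are
  normalized by the optimal length (0.10 m). For lengthening (`V < 0`) the
  factor is clamped at 1 — no eccentric force enhancement — which keeps the
  per-step residual monotone and is inconsequential for the lifting
  scenarios, where sustained lengthening only occurs after the outcome is
  decided. The measured maximal shortening velocity (7.60 lengths/s) is
  deliberately *not* used in the dynamics; it differs from the Hill-implied
  8.02 because a pooled hyperbola fit need not pass through the measured
  intercept. It is used only to express load velocities as %V_max in
  reports.
* **Activation** `a(t)`: a sampled, linearly interpolated array, constant
  at 1 beyond its last sample. The default is synthetic (below).

## Integration

Fixed 100 µs steps (`dt`, configurable). Each step solves a scalar root
problem in the end-of-step tendon elongation `e₂`:

```
(k e₁ + k e₂)/2  =  F_muscle(t_mid, (L₁+L₂)/2, V_m)          (residual = 0)
```

with the load updated trapezoidally — the step-average tendon force drives
the velocity update, the step-average velocity the position update — and
`V_m = (v₁+v₂)/2 + Δe/dt` the step-average muscle shortening velocity
(reducing to `Δe/dt` exactly while the load is caught or grounded). The
residual is strictly increasing in `e₂` because the `1/dt` velocity
sensitivity of the force–velocity factor dominates every other dependence,
so the root is unique; it is found by an expanding bracket from the
previous elongation followed by the Illinois variant of regula falsi, to a
force residual below `solver_tolerance` (default 1 nN).

The midpoint/trapezoidal coupling was chosen over a simpler semi-implicit
scheme for two reasons: it makes the trapezoid work integrals (muscle work,
work on the load, tendon stored energy) *identities* of the discrete
update, so `muscle work = load ΔKE + ΔPE + tendon energy` holds to
round-off rather than to O(dt); and it is second-order, which is what lets
the apex pass a dt-halving test at 0.1% in the violent catch-release
scenarios. Phase events (catch release, liftoff, grounding) are resolved at
step boundaries and remain first-order; their energetic effect is small
because force is continuous through each of them.

Phases advance caught → grounded → airborne. Liftoff occurs when the tendon
force exceeds the load's weight; a descending load that reaches the ground
is re-grounded (velocity zeroed) by re-solving the step. At a stretched
start (e.g. 120% L0) a static pre-strain `k·e₀ = passive force` is solved
by bisection before stimulation begins, with the ground supplying the
reaction.

**Termination.** A run ends when (a) the active force–length factor reaches
zero at the end-of-step length (`active_force_exhausted`); (b) the solved
force reaches zero after the muscle has produced force at least once
(`force_zero` — tendon recoil complete or the load outrunning the MTC;
zero force *before* any force has developed is an idle early-activation
step, not an ending); (c) the safety cap `max_time` elapses; or (d) the run
is provably finished (`stalled`): either a grounded load whose activation
has saturated, strain stopped changing and force sits below the weight —
it can never lift — or an airborne load whose apex has not improved for
0.5 s of saturated-activation bouncing. With sustained full activation a
moderately loaded MTC settles into a damped hover (force = weight) rather
than exhausting itself; the reported apex is therefore the running maximum
of the instantaneous ballistic apex `y + max(v,0)²/2g` over the airborne
phase, which coincides with the at-termination ballistic extrapolation
whenever the run ends mid-ascent.

**Bookkeeping.** Work increments use step-average force times the relevant
displacement: muscle work `F̄·(Δy+Δe)`, work on the load `F̄·Δy`, tendon
energy `F̄·Δe` (exactly ½kΔ(e²) for the linear spring). Muscle power is
`F·V_m`, MTC power — the work rate delivered to the load — is `F·v_load`;
surfaces labeled "peak MTC power" use the latter, which is what exceeds the
muscle's isotonic optimum during recoil. Work before/after release splits
the cumulative muscle work at the catch delay.

## Sweeps

Two-axis grids sample exact endpoint-inclusive ranges: linear for catch
delay and initial muscle length, geometric for tendon modulus/length/area
and load mass, 100 increments per axis at full scale. Each cell is one
deterministic simulation (traces off); re-running reproduces surfaces
bit-identically, and only the product `E·A/L` matters, so equal-stiffness
cells agree to machine precision. Argmax ties break toward the smallest
(row, column) index. Pearson correlations between surfaces use all cells
by default, including never-lifted zero-height cells (`drop_nan` only
removes failed cells); whether zero cells are included is exposed to the
caller by masking the arrays. Improvement percentages compare against a
functionally rigid reference: the stiffest corner cell for modulus × area
sweeps, the largest-area cell in the same load row for load sweeps.

Quick-look grid sizes (tests ~20×20, the acceptance script 40 per axis by
default, `--n-grid` up to 100) are the package's default working scale;
surface summaries (argmax products, correlations, gain orderings) are
stable across these sizes because the surfaces are smooth in log-parameter
space.

## Synthetic data and the default activation curve

No in vitro records are deposited, so characterization data are generated
around known truth: force–length samples span 60–130% L0 (emulating 1 mm
increments on a 10 cm muscle), force–velocity samples span 0–90% of the
unloaded velocity, tetanic rises are sampled at 5 kHz for 0.5 s. Noise is
additive i.i.d. Gaussian (defaults σ = 0.05 force–length, 0.03
force–velocity, 0.02 tetanus — chosen to visually match the scatter of
published sartorius datasets); every generator is a pure function of
(truth, n, seed). Force–velocity samples are clipped to [0, 1], which
introduces a small downward bias near the isometric point; the fit
tolerances absorb it.

The measured activation array is available only graphically, so the
default curve is the simplest monotone saturating family consistent with
two facts the simulated system must reproduce: catch delays up to ~25 ms
are null at the 20%-P0 load (the curve crosses 0.20 near 25 ms) and
improvement with delay is mostly complete by 200 ms (near saturation).
`a(t) = (1 − exp(−t/τ))^p` with τ = 42 ms, p = 2 satisfies both
(`a(25 ms) = 0.201`, `a(200 ms) = 0.983`); τ and p are config-exposed so an
alternative digitization can be swapped in. Every activation-sensitive
quantity (lift gains, work ratios, peak velocities) depends on this curve,
which is why the corresponding checks are ordering/tolerance checks rather
than exact reproductions — the calibration-arithmetic identities and the
optimal stiffness ridge are activation-insensitive and come out at the
printed values.

## Fitting

Force–length: ordinary least-squares cubics on the raw pooled samples
(the passive zero-clamp below L0 is a simulation-time constraint, not a
regression constraint), with r² reported and rank-deficiency rejected.
Force–velocity: nonlinear least squares of the normalized Hill form with a
small restart grid; returns `a_rel`, `b` and the implied `b/a_rel`.
Activation: each tetanus is normalized to its plateau (mean of the final
tenth — a single-sample maximum is a biased-high order statistic), records
truncated to the shortest, averaged, clipped to [0, 1], monotonized by
running maximum (the solver requires non-decreasing activation; a measured
mean need not be monotone) and rebased to start at exactly 0 and saturate
at exactly 1. Pooling weights every sample equally. On noiseless data all
fits are exact round trips; under the default noise the estimators are
consistent (error shrinks with n), and the full generate → fit → simulate
pipeline reproduces truth apex heights within 2% at σ = 0.02, n = 60.

## Known limitations

* The activation curve is a calibrated stand-in; absolute work/height
  values shift with its shape even though orderings and ridge locations do
  not.
* No eccentric force enhancement, history dependence (shortening
  deactivation, stretch enhancement), fiber-type or temperature effects.
* Tendon is linear-elastic with no hysteresis; energy return is perfect.
* Event handling (liftoff, release, termination) is step-quantized;
  sub-step event location is not attempted.
* Sweeps larger than two simultaneous axes, and inverse problems
  (recovering activation from motion), are out of scope.
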