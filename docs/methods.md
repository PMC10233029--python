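# Methods

## Model

A runner racing for a fixed duration `T` is described by four states:
velocity `V` (m/min), fat energy `E_F` (KJ/kg), glycogen energy `E_G`
(KJ/kg), and in-transit nutrition `N` (KJ). Velocity follows the classic
force-balance `dV/dt = f − V/τ` with propulsion force per unit mass
`f ∈ [0, f_max]` and a linear internal resistance with time constant `τ`.
Mechanical work drains the two energy stores at the mass-specific rate
`a·sm·f·V` (KJ/(kg·min); `a = 1/1000` converts J→KJ and `sm = 1/3600`
closes the squared seconds-to-minutes unit conversion — with `f` in
m/min² and `V` in m/min, `f·V` is m²/min³ and the factor 1/3600·1/1000
brings it to KJ/(kg·min)). The split between the stores is set by the
fuel-allocation curve `glyc(V/VVO2max)` (below). Nutrition enters `N` as
calorie pulses `s(t)` (gels, 1 kcal = 4.184 KJ), is absorbed into
glycogen at the first-order rate `c₄·N` (scaled per kg by `c₃ = 1/m`),
and leaks at rate `d·N` to processes unavailable to the muscles. Fat is
never replenished during a race.

Default parameters describe an elite 55 kg runner: `τ = 1/60` min,
`d = 0.005` /min, `c₄ = 1/6` /min, `VVO2max = 402` m/min,
`f_max = 36000` m/min², `E_F(0) = 3439` KJ/kg, `E_G(0) = 144` KJ/kg.
`E_F(0)` is taken at face value; it is far from binding in any scenario
(a two-hour race uses ~50 KJ/kg of fat). Runner-level inputs are mass,
VVO2max, initial glycogen, uptake rate, and the lactate-capacity class.

## Fuel-allocation curve

`glyc(x)` maps relative intensity `x = V/VVO2max` to the glycogen share
of the work rate. Physiological anchors: ~0.30 at rest, anaerobic
contribution growing past ~0.6, and exactly 1 at `x = 1`. Three curve
shapes encode lactate capacity (VLa): a "good" (low-VLa, fat-sparing)
runner burns a smaller glycogen share at every intensity than "average"
or "bad", so the curves are pointwise ordered.

Each curve is a monotone shape-preserving piecewise cubic (PCHIP) through
five knots at x = 0, 0.3, 0.6, 0.8, 1, clamped to its endpoint values
outside [0, 1]. A plain natural-spline mode exists for fidelity
experiments but is not the default, because an unconstrained cubic spline
can overshoot [0, 1] between knots and an allocation fraction must not.
Construction validates monotonicity and range on a 1000-point grid.

The knot ordinates are only partially determined by physiology, so each
curve carries one free ordinate — the knot nearest the anchor scenario's
race intensity — pinned by calibration: a scalar bisection tunes the
ordinate until the anchor scenario's *optimized* distance matches its
target (good: the world-record race, 42.5 km; average: the unfueled
T=135 race, 40.0 km; bad: the unfueled T=135 race, 37.8 km; relative
tolerance 0.2%). Distance is monotone decreasing in the ordinate, so the
bisection is well-posed; calibration is idempotent and the result is
serialized with a self-describing record. All other reported scenarios
are then validations, not fits. The starting ordinates were chosen once
from the shape constraints (the bad curve's low-intensity knot sits at
0.46 so that the calibrated curves preserve the good ≤ average ≤ bad
ordering everywhere, including near the PCHIP endpoints, where a steep
neighboring segment can otherwise collapse the boundary derivative).

## Discretization and stability

Controls live on a uniform mesh of `M` nodes (`M = T + 1`, i.e. 1-minute
steps, for all standard scenarios); `h = T/(M−1)` steps the states and
`δ = T/M` is kept as the objective's quadrature weight. The dynamics are
defined by their forward-Euler discretization, but `τ ≈ 1 s` makes the
raw velocity recursion unstable at `h = 1` min, so each mesh interval is
integrated with interior Euler sub-steps sized at half the tightest
stability bound (`min(τ, 1/(d+c₄))`), giving 120 sub-steps of 0.5 s per
minute. Controls stay piecewise-constant per mesh interval, which makes
the interior velocity and nutrition recursions affine with closed-form
sub-step solutions; the whole integration and the exact jacobian of the
discrete map with respect to the force schedule are evaluated with dense
array operations. Under these contractions `V ≥ 0` and `N ≥ 0` hold
automatically, `E_F` is non-increasing, and the discrete energy ledger

    (E_F(0)−E_F(t)) + (E_G(0)−E_G(t)) = Σ work − Σ absorbed

is an algebraic identity, audited to 1e−9 relative on every trajectory.
The simulator never clips negative energies; it flags the first offending
node, since feasibility belongs to the optimizer.

## Optimal control problem

For a fixed nutrition strategy, maximize the left-rectangle distance
`h·Σₖ Vₖ` subject to the discrete dynamics, force bounds, and
`E_F, E_G ≥ 0` (state upper bounds are the tightest implied by the
dynamics: `V ≤ VVO2max`, `E_G ≤ E_G(0) + c₃·(total KJ)`, `E_F ≤ E_F(0)`,
`N ≤ total KJ`). The optimum is singular — the objective is locally flat
in the force over most of the race — which produces numerical chattering
unless regularized, so the objective is

    J = −δ Σ Vₖ + p Σ (ζᵢ + ιᵢ)

with the nonnegative split `ζᵢ − ιᵢ = fᵢ₊₁ − fᵢ` bounding the force's
total variation, and `p = 0.5` by default. The transcription stacks
`[f, E_F, E_G, V, N, ζ, ι]` with the dynamics as equality constraints.

Because the states are uniquely determined by the force schedule (the
nutrition path does not depend on `f` at all), the solver eliminates them
and works in the reduced space `[f, ζ, ι]` — an exact projection of the
feasible set: linear TV-split equalities, state-bound inequalities
evaluated through the simulator, box bounds. All variables are scaled to
O(1) (forces by `f_max`, energies by their capacity, the objective by
`δ·(M−1)·VVO2max`, important because raw magnitudes span 10⁰–10⁴), and
scipy's SLSQP runs with exact analytic gradients (ftol 1e−10, up to 3000
iterations). The default initial guess is the largest feasible
constant-force schedule found by bisection ("warm"); the historical
all-`f_max` guess is available behind a flag, and solutions are
guess-independent at tolerance (tested). After the solve, the force is
clipped to bounds and, if a state bound is violated at solver-tolerance
level, uniformly scaled down by a bisected factor so converged solutions
satisfy `E_G, E_F ≥ 0` exactly; the full decision vector is then
reconstructed and every transcription constraint re-verified (converged
status requires scaled violation ≤ 1e−6). Distance is reported with the
`h` weight; the `δ`-weighted twin (<1% different) is logged alongside.

The outer problem — choosing among the 16 catalogued gel strategies — is
an exhaustive enumeration; ties within 1e−6 km are reported co-optimal.
A brute-force oracle cross-checks optimality on tiny instances (≤10 mesh
steps, ≤8 discrete force levels) by enumerating every ladder schedule
with the same integrator; the NLP searches a superset of those schedules
and must match or beat the oracle.

## Nutrition strategies

The catalogue holds sixteen strategies: 0–24 evenly spread 100-kcal
gels, single early/late gels, two-early-two-late, and equal-calorie
redistributions (200/250/50-kcal variants). Evenly spread pulses land at
`round(j·T/(n+1))` minutes; "early"/"late" are conventions at 15%/85% of
`T` (10/20/80/90% for the two-early-two-late schedule). The world-record
scenario uses its explicitly specified gel times (minutes 20, 46, 71,
97). Each pulse delivers its full energy within one mesh step, so
calories are conserved exactly and pulse minutes are mesh-independent;
absorption dynamics are the nutrition compartment's job. The per-step
source bound is one 250-kcal gel per minute (1046 KJ/min), the largest
catalogued gel — the bound exists for compactness of the admissible set
and never binds.

## Problem sizes and runtime

All standard solves use the printed mesh (M = 121–216 nodes, ~360
reduced variables) and complete in under a second each; full calibration
plus every reported scenario runs in well under a minute on one core. The
property tests use shorter horizons (T = 5–30 min) where they probe
structure rather than reported outcomes, and the oracle comparison uses
T = 8 with a 4-level ladder (4⁸ schedules).

## What the tests do and do not show

The model's validation targets are the printed outcomes of the study
conditions, not field data: one anchor per fuel curve is fit by
construction, and the remaining table rows (different gel counts,
timings, VLa classes, durations, masses, VVO2max values) are checked as
out-of-sample validations at 3%. Passing therefore shows the model class
plus the documented calibration reproduces the reported race economics;
it does not show the curves are physiologically correct for any
individual runner, and real races add effects the model omits by design:
no gastrointestinal tolerance limit (distance grows essentially linearly
with gel count — by construction, taking 24 gels "wins"), no explicit
lactate state, no terrain, temperature, hydration, or body-mass loss.

## Known limitations and edge cases

- The velocity bound `V ≤ VVO2max` caps achievable distance at
  `VVO2max·T`. For slow long-duration scenarios the model runs
  unrealistically close to that ceiling, and one reported 210-minute row
  lies above it entirely; table reproduction marks such rows
  `velocity_bound_limited` instead of failing them.
- With `h = τ` a single raw Euler step has O(1) transient error; the
  closed-form check `V = fτ(1−e^{−t/τ})` is therefore asserted as
  first-order convergence under sub-step refinement (error ratios ≈ 2)
  and sub-0.5% node agreement for the default integrator.
- At `p = 0` the optimizer may return any member of the singular
  solution set; TV-vs-penalty monotonicity is asserted on an instance
  whose optimum is genuinely two-phase (near-empty initial glycogen, one
  mid-race gel).
- Degenerate inputs: `E_G(0) = 0` with no nutrition yields the rest
  solution (distance 0); pulse collisions on one mesh step are summed
  with a warning; non-finite controls raise with the offending index.
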