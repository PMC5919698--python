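# Methods

## The model

`workloop` simulates a Hill-type muscle actuator working in series against a
damped harmonic oscillator, the simplest load that mixes inertial, elastic
and viscous components the way the environment loads a locomotor muscle. The
muscle is a bundle of parallel fibres of optimal length `l0` with a
contractile element (CE) and a parallel elastic element (PEE); there is no
tendon, no pennation, and the muscle tissue itself is treated as massless in
the dynamics (its mass enters only the power normalization). Motion is
one-dimensional: the muscle length is `l_m = l_tot − x`, where `x` is the
position of the oscillator mass and `l_tot = 2 l0` is the fixed total system
length.

The equation of motion for the displacement `Δx = x − x0` about the
oscillator resting length `x0` is

    m Δx¨ + b Δx˙ + k Δx = F_m,
    F_m = F0 ( a · F_A(l̂) · F_V(v̂) + F_P(l̂) ),

with normalized length `l̂ = l_m / l0` and normalized velocity
`v̂ = (dl_m/dt) / (l0 ε̇0)`, where `ε̇0` is the maximum shortening strain
rate (so `v̂ = −1` is unloaded maximal shortening). Shortening means `x`
increasing, hence `v̂ < 0` on the concentric branch.

Activation `a` follows excitation `u` through the first-order bilinear lag

    da/dt = ( u − a (β + u (1 − β)) ) / τ_act,

whose rise rate under constant `u` is `(β + u(1−β))/τ_act` toward the steady
state `a_ss = u/(β + u(1−β))`; with `β ≤ 1` deactivation is slower than
activation. `u` is a square wave with frequency `f`, duty cycle `D` and
amplitude `u_max`; the on-phase starts at the beginning of each cycle (the
phase convention is immaterial for steady-state outputs).

### Muscle geometry

The muscle is a cylinder of aspect ratio `R = l0 : diameter`:

    A = (π/4)(l0/R)²,   F0 = σ0 A,   m_m = ρ l0 A.

Defaults (SI): `l0 = 0.02 m`, `σ0 = 225 kPa`, `ρ = 1060 kg/m³`, `R = 100`,
giving `F0 ≈ 7.07 mN` and `m_m ≈ 0.666 mg`. `ε̇0` is 10 1/s for a fast and
5 1/s for a slow muscle, with `τ_act` 0.025 s and 0.045 s respectively and
`β = 0.6`.

### Oscillator linkage

Rather than choosing `m`, `k`, `b`, `x0` freely, they are tied to the muscle
through dimensionless fractions with physiological meaning:

    ω_n = 2π c1 f_d     (natural frequency as a fraction of the drive),
    m   = c2 F0         (load mass per unit muscle force, c2 in kg/N),
    x0  = c3 (l_tot − l0),
    b   = √(4 m k)      (exactly critical damping),

so `k = m (2π c1 f_d)²` and `b = 4π m c1 f_d`. In code `k` is computed as
`b²/(4m)` so that the critical-damping identity holds to rounding (within
2 ulp — the divide/multiply round trip prevents bit-exact equality for
arbitrary `m`).

The default linkage values shipped with the package were produced by the
package's own global optimizer (see below) for a fast muscle at full
excitation with the driving frequency free:

    c1 = 1.0750,  c2 = 0.1704 kg/N,  c3 = 0.3089,
    f_d = 1.8316 Hz,  D = 0.5859,

achieving `P* ≈ 61.5 W/kg`. With these defaults the steady-state muscle
operates between `l̂ ≈ 0.83` and `1.30` — ascending limb and plateau of the
active force–length curve — and the work loop is traversed in the
power-generating direction.

## Intrinsic curves

The force–velocity and active force–length relationships are composite
cubic Bézier curves (two segments each); the passive force–length
relationship is a single cubic segment. Control-point abscissas are
non-decreasing, which makes the abscissa component of each segment monotone
in the curve parameter, so evaluation at an abscissa reduces to a 1-D root
solve. The solve is a safeguarded Newton iteration (bisection fallback)
run to rounding level, well inside the documented 1e-12 abscissa tolerance.
Monotonicity is enforced at construction, so the root is unique; at an
interior join the left segment claims the shared abscissa.

Constraints fix most control-point coordinates:

- **Force–velocity**: concentric limb from `(−1, 0)` to `(0, 1)`, symmetric
  about the line `F = −v` (the inner control point `(p, q)` implies its
  mirror `(−q, −p)`); eccentric limb from `(0, 1)` to `(1, F_max)` with its
  initial slope matched to the concentric slope `(1+p)/q` at `v̂ = 0` and
  zero slope at the plateau. Outside `[−1, 1]` the force is held constant at
  0 and `F_max`. The single point where C1 continuity is not required is the
  concentric end at `v̂ = −1`: the combination of the zero intercept and the
  symmetry constraint makes a continuous derivative there impossible.
- **Active force–length**: ascending and descending limbs join at `(1, 1)`
  with zero slope from both sides; zero force and slope at both endpoints;
  zero outside.
- **Passive force–length**: zero force and slope at the slack length 0.7;
  beyond 1.65 the curve continues linearly with the slope of the chord
  between its last two control points, which equals the cubic's end slope,
  so the extension is C1.

Free parameters not fixed by constraints default to values giving a
Hill-like concentric curvature (crossing the symmetry diagonal near
`−v̂ ≈ 0.31`, isometric slope ≈ 5) and typical force–length spans
(ascending start 0.45, descending end 1.65, eccentric plateau `F_max = 1.5`
— a mid-range value among published eccentric plateaus; all configurable).
Published control-point tables can be dropped in through the CSV loader,
which enforces only the structural invariants.

### Fitting

`fit_curve` maximizes `r² = 1 − SSres/SStot` over the free control-point
coordinates with seeded differential evolution inside box bounds chosen so
that every candidate inside the box satisfies the monotonicity constraints,
followed by a local polish. Degenerate data (all ordinates equal) is
rejected. Noiseless data sampled from a curve in the feasible box is
recovered to well under 1% parameter error; results are bit-reproducible
for a fixed seed.

## Simulation and steady-state extraction

The coupled ODE in `(x, v, a)` is integrated with an adaptive high-order
explicit Runge–Kutta method (DOP853), restarted at every excitation edge so
the square-wave discontinuity never crosses an adaptive step, with dense
output sampled on a uniform grid of 2048 intervals per cycle.

Default tolerances are `rtol = 1e-9`, `atol = 1e-12`. These are chosen so
that the dimensionless steady-state traces of geometrically similar runs
(λ = 1 vs 10) agree to better than 1e-6 — the headline similarity property;
at looser tolerances (1e-8/1e-10) the residual transient and integration
error leave channel deviations of order 1e-6, right at the contract.

Per-cycle net work is `W_net = ∮ F_m dx` (trapezoidal rule on the dense
cycle grid), the work the muscle does on the load; over a closed
steady-state cycle it equals the damper dissipation `∮ b Δx˙² dt` because
the spring is conservative and the kinetic energy is periodic. Steady state
is declared when at least 8 cycles have run and the last three consecutive
per-cycle work differences are below 1e-6 relative; critical damping makes
this converge within ~10 cycles (the transient contracts by roughly e⁻⁴ per
cycle at the default linkage). The reported mass-specific power

    P* = W_net f / m_m

is averaged over the last three cycles to smooth residual drift. The
instantaneous muscle power is `F_m · v_m` with `v_m = dl_m/dt`; its cycle
integral equals `−W_net` (the sign convention makes a power-generating
muscle report positive `P*`).

Blow-ups (`l_m ≤ 0` or non-finite state) raise an error carrying the last
valid state; the optimizer maps them to a large penalty.

## Scaling and similarity

Geometric scaling by a length factor λ holds stress, density and
mass-specific power constant, which forces `F0 ∝ λ²`, `m_m ∝ λ³`, both time
scales to 1, and the oscillator constants `m`, `b`, `k`, `x0` all ∝ λ. The
three dimensionless groups `m x0/(F0 t_h²)`, `b t_h/m`, `k t_h²/m` are then
invariant, so the dimensionless trajectories of the root and scaled systems
coincide and `P*` is size-invariant, while dimensional lengths and
velocities scale with λ, forces with λ², powers with λ³.

When a configuration stores the linkage fractions, scaling multiplies `l0`
by λ and divides `c2` by λ (`c2 = m/F0` carries units kg/N; `λ_m = λ` and
`λ_F0 = λ²` force `λ_c2 = λ⁻¹`); `c1`, `c3`, `f_d` and all time-domain
parameters are untouched. Similarity checks nondimensionalize the last
cycle of each run, resample onto a common 2048-point phase grid by monotone
interpolation, and report the maximum absolute deviation per channel
against a default tolerance of 1e-6 (matched to the integrator tolerances).

## Linkage optimization

`optimize_linkage` maximizes `P*` over `(c1, c2, c3, f_d, D)` — or over
`(c1, c2, c3, D)` with `f_d` tied to a prescribed excitation frequency —
using seeded differential evolution followed by a bounded Nelder–Mead
polish. Gradient-based polish is deliberately avoided: the objective passes
through an adaptive ODE solve whose ~1e-6 noise corrupts finite-difference
gradients. Default bounds are `c1 ∈ [0.05, 2]`, `c2 ∈ [1e-3, 1e2] kg/N`
(searched on a log10 scale because it spans five decades),
`c3 ∈ [0.05, 0.95]`, `f_d ∈ [0.1, 5] Hz`, `D ∈ [0.05, 0.95]`. During the
search the simulation runs at reduced accuracy (256 samples/cycle,
rtol 1e-6, work tolerance 1e-4) to keep the budget tractable; the winner can
be re-evaluated at full accuracy. The result records every evaluation, the
best-so-far trace (non-decreasing by construction) and which bounds are
active at the optimum.

Whether the linkage should be re-optimized per contractile condition or
optimized once for the fast muscle and reused is genuinely open; both modes
are supported, and the condition-grid analyses use per-condition
optimization (each condition gets the load that favours it), while the
package defaults come from the single fast-muscle optimization.

## What the synthetic fixtures do and do not emulate

The fixture generator produces: digitized-style curve data (points sampled
from the default curves with optional Gaussian ordinate noise), a
linear-plant configuration (constant curves + instantaneous activation)
whose periodic steady state has a closed form, an elliptical work-loop
trace with known enclosed area `πAB`, and the 16-condition grid
(f ∈ {0.5, 1, 2} Hz paired with fibre speed as in the published grid,
× u_max ∈ {0.1, 1} × λ ∈ {1, 10}). The linear-plant fixture runs at
`u_max = 0.25`: with the intrinsic curves replaced by constants nothing
limits the travel of the mass, and the full default drive would push the
system outside its physical length.

Synthetic curve data shares the constrained functional form of the
generating curves, so fit-recovery results demonstrate the correctness of
the fitting machinery, not the adequacy of cubic Bézier segments for any
particular muscle's data. Likewise the oscillator is an idealized stand-in
for an *in vivo* load: passing similarity and energy-balance checks shows
internal consistency of the framework, not fidelity to a specific
experimental preparation.

## Numerical choices and degenerate inputs

- Segment inversion: safeguarded Newton, bracket [0, 1], run to rounding.
- Quadrature: trapezoidal on 2048 intervals/cycle; both the work and the
  power-integral quadratures are second order, so identities between them
  are resolution-limited at ~(1/2048)² ≈ 2e-6 relative and tighter checks
  use denser grids.
- Duty cycle `D = 1` is accepted by the protocol type as the degenerate
  always-on excitation (used by static-equilibrium checks); configuration
  files require `0 < D < 1`.
- `detect_steady_state` compares successive works with a relative tolerance
  and a small absolute floor (1e-15 J) so an identically zero work sequence
  (no excitation) is steady from the first pair.
- All randomness (fitting, optimization, fixtures) flows from explicit
  integer seeds; repeated runs are bit-identical.

## Problem sizes used in the shipped analyses

The acceptance script and the end-to-end tests run the root model at full
accuracy (≤ 100 cycles, 2048 samples/cycle; in practice 8–11 cycles) and
the per-condition optimizations at a reduced budget (popsize 5, 8
generations plus a 60-evaluation polish, ≈ 240 objective evaluations per
condition at search accuracy). The orderings reported (faster muscle →
higher `P*`; higher excitation → higher `P*`) are insensitive to this
budget; publication-grade optima use the larger default budget
(≈ 2000–4000 evaluations), as was done to freeze the package defaults.

## Known limitations

- No series elastic element, pennation, history dependence, or fibre-type
  recruitment; the CE/PEE model is deliberately minimal.
- The muscle is massless in the dynamics; internal tissue inertia effects
  are outside this framework's scope.
- The published per-condition power values depend on supplementary
  optimized parameters and curve control points that are not part of this
  package; with its own defaults the package reproduces the qualitative
  structure (orderings, scale invariance) and the order of magnitude of
  `P*`, not those exact numbers. Drop-in CSV control points and explicit
  linkage parameters are supported for users who have them.
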