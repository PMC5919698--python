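# workloop

Forward-dynamics simulation of a Hill-type muscle actuator driving a
critically damped harmonic oscillator through cyclic contractions.

Work-loop experiments — cyclically contracting a muscle against a load and
measuring the closed force–length path — are the standard way to study how
muscles produce mechanical power during locomotion. `workloop` provides the
computational counterpart: a muscle model (contractile element + parallel
elastic element, no tendon) in series with a mass–spring–damper load,
driven by square-wave excitation through first-order activation dynamics.
It is aimed at muscle physiologists and biomechanists who want to test
muscle-model formulations under controlled cyclic loading, at any body
size.

The core quantities, in the field's standard notation:

- Muscle force: `F_m = F0 (a · F_A(l̂) · F_V(v̂) + F_P(l̂))`, with
  `l̂ = l_m/l0` and `v̂ = (dl_m/dt)/(l0 ε̇0)`; the intrinsic curves `F_A`,
  `F_V`, `F_P` are constrained composite cubic Bézier curves.
- Load dynamics: `m Δx¨ + b Δx˙ + k Δx = F_m`, with `b = √(4mk)`
  (critically damped) and the load tied to the muscle by dimensionless
  linkage fractions `ω_n = 2π c1 f_d`, `m = c2 F0`, `x0 = c3 (l_tot − l0)`.
- Activation: `da/dt = (u − a(β + u(1−β)))/τ_act` under square-wave
  excitation with frequency `f`, duty cycle `D`, amplitude `u_max`.
- Output: per-cycle net work `W_net = ∮ F_m dx` at steady state and the
  cycle-average mass-specific power `P* = W_net f / m_m` (W/kg).

The system scales geometrically while preserving kinematic and dynamic
similarity: forces grow with λ², powers with λ³, but every dimensionless
trace and `P*` itself are size-invariant. The linkage fractions and duty
cycle can be globally optimized to maximize `P*`; the shipped defaults come
from exactly that optimization for a fast muscle at full excitation.

## Worked example

```python
import workloop as wl

cfg = wl.RunConfig()                 # root model: fast muscle, optimized linkage
result = wl.simulate_config(cfg)
loop = wl.work_loop(result, -1)
print(result.P_star, loop.net_work, result.n_cycles_run)
```

Running `python examples/simulate_workloop.py` prints:

```
cycles run            : 8 (steady: True)
net work per cycle    : 2.2351e-05 J  (counter-clockwise loop)
damper dissipation    : 2.2351e-05 J
mass-specific power P*: 61.466 W/kg
muscle length range   : 0.833 - 1.296 (units of l0)
peak muscle force     : 0.501 F0
```

The 2-cm root muscle settles into its steady-state cycle after 8 cycles and
delivers 61.5 W per kilogram of muscle. The net work exactly matches the
damper dissipation — over a closed cycle the spring returns what it stores
and the kinetic energy is periodic, so everything the muscle does ends up
in the damper. The counter-clockwise loop in the (length, force) plane is
the signature of a power-generating muscle: high force while shortening,
low force while being re-lengthened.

Other examples (each a short narrative script): `scale_invariance.py`
(λ = 1 vs λ = 10 runs agree channel-by-channel to ~1e-8 in dimensionless
form while forces scale 100× and powers 1000×), `fit_intrinsic_curves.py`
(refitting the constrained force–velocity curve to noisy digitized data),
and `optimize_linkage.py` (a small-budget linkage optimization).

A thin CLI wraps the same functionality:

```
workloop simulate --config cfg.json --out outdir/
workloop optimize --eps0 10 --umax 1 --seed 0 --budget 2000 --out best.json
workloop fit-curves --data fv.csv --curve force_velocity --out fits/
workloop scale-check --lambda 10 --out report.csv
workloop fixtures --kind table3_grid --out grid/
```

Configurations are single JSON files; every key has a documented default,
so `{}` runs the root model. The 16-condition grid (cycle frequency ×
fibre speed × excitation × geometric scale) is generated by
`workloop fixtures --kind table3_grid`, and published Bézier control-point
tables can be dropped in as CSV files via the `curves` config section.

See `docs/methods.md` for the model details, numerical choices and
limitations.

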