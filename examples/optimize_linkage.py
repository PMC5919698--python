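"""Optimize the oscillator linkage for maximum mass-specific power.

Searches (c1, c2, c3, D) at a fixed 1 Hz cycle frequency for a fast muscle
at full excitation, using a small demonstration budget (the package default
budget is larger). Prints the best linkage and the power it achieves.
"""

import workloop as wl

spec = wl.OptimizationSpec(
    eps0_dot=10.0,   # fast fibres
    u_max=1.0,       # full excitation
    f_hz=1.0,        # drive frequency tied to the excitation frequency
    seed=0,
    popsize=5, maxiter=8, polish_maxfev=60,
)
result = wl.optimize_linkage(spec)

print(f"best P*        : {result.P_star:.3f} W/kg")
for k, v in result.params.items():
    flag = result.active_bounds[k]
    print(f"  {k:3s} = {v:8.4f}" + (f"   (at {flag} bound)" if flag else ""))
print(f"evaluations    : {result.n_evaluations}")
finite = result.trace[result.trace > -1e5]  # skip penalized early candidates
print(f"best-so-far P* : {finite[0]:.3f} -> {finite[-1]:.3f} W/kg")

# c1 sets the oscillator natural frequency relative to the drive, c2 the
# load mass per unit muscle force, c3 the resting length of the oscillator,
# and D the fraction of the cycle the muscle is excited.
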