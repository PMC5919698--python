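"""Geometric scaling with preserved dynamic similarity.

Runs the root model and a 10x geometrically scaled copy (stress and density
held constant, oscillator constants rescaled with the length factor), then
compares their dimensionless steady-state traces. Lengths should scale with
lambda, forces with lambda^2, powers with lambda^3, while every
dimensionless channel and the mass-specific power P* are identical.
"""

import numpy as np

import workloop as wl

cfg = wl.RunConfig()
root = wl.simulate_config(cfg)
scaled = wl.simulate_config(wl.apply_scaling(cfg, 10.0))

report = wl.check_similarity(root, scaled, tol=1e-6)
print(report.to_string(index=False))
print(f"\nP* root   : {root.P_star:.6f} W/kg")
print(f"P* scaled : {scaled.P_star:.6f} W/kg")
for ch, p in (("F_m", 2), ("power", 3), ("l_m", 1)):
    ratio = np.max(np.abs(getattr(scaled, ch)[-1])) / np.max(np.abs(getattr(root, ch)[-1]))
    print(f"{ch:6s} peak ratio = {ratio:10.4f}  (expected 10^{p} = {10.0**p:g})")

# Deviations are bounded by the integrator tolerance (~1e-7); the dimensional
# outputs scale with the stated powers of lambda while P* is size-invariant.
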