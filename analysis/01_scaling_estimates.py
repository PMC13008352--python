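#!/usr/bin/env python
"""Closed-form scale estimates of the poroelastic cell response.

Computes the deformed-region length scale L = sqrt(d delta), the fluid
efflux time t_p = L^2/D, the tension/elasticity crossover length
l = gamma/E, the vertical relaxation time tau_z = l delta_z/(kE), and the
pore-size scaling chain under a 40% osmotic volume decrease.  Writes
results/scaling.json.
"""

import json
from pathlib import Path

from porocell import PoreScalingParams, pore_scaling, scaling_estimates

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# AFM indentation: ~4 um contact diameter, ~2 um depth, D ~ 40 um^2/s
indent = scaling_estimates(d=4.0, delta=2.0, D=40.0)
# cortical tension ~1 mN/m over a ~100 Pa cytoplasm
tension = scaling_estimates(gamma=1e-3, E=100.0, delta_z=0.5, k=0.1)

xi72 = pore_scaling(PoreScalingParams(xi=0.72, xi0=1.0))
xi77 = pore_scaling(PoreScalingParams(xi=0.77, xi0=1.0))
formula = {
    phi: pore_scaling(PoreScalingParams(alpha=0.6, phi=phi)) for phi in (0.42, 0.6)
}

payload = {
    "L_um": indent.L,
    "t_p_s": indent.t_p,
    "l_um": tension.l,
    "tau_z_s": tension.tau_z,
    "tp_ratio_at_xi_0.72": xi72[1],
    "tp_ratio_at_xi_0.77": xi77[1],
    "xi_ratio_formula_alpha0.6": {str(k): v[0] for k, v in formula.items()},
}
(OUT / "scaling.json").write_text(json.dumps(payload, indent=2))

print(f"deformation length scale      L     = {indent.L:.2f} um")
print(f"poroelastic efflux time       t_p   = {indent.t_p*1e3:.0f} ms")
print(f"tension/elasticity crossover  l     = {tension.l:.1f} um")
print(f"vertical relaxation time      tau_z = {tension.tau_z*1e3:.0f} ms")
print(
    "pore-size chain: xi/xi0 in [0.72, 0.77] slows fluid efflux "
    f"{xi77[1]:.2f}-{xi72[1]:.2f}-fold, well short of the ~3.5-fold slow-down"
    " seen under hyperosmotic shock - volume change alone under-predicts it."
)
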