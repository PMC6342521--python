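"""Viscosity-limited particle diffusivity and intestinal Weissenberg numbers.

Aggregation is collision-limited at short times: as polymer concentration
rises, the Huggins viscosity rises and the Stokes-Einstein-Sutherland
diffusivity of the particles falls, slowing aggregation kinetics even where
the thermodynamic well is deep.  The Weissenberg number Wi = shear rate x
relaxation time gauges whether elastic stresses matter during peristalsis.
"""

import numpy as np

import gutfloc as g

# [η] from the PEO Mark-Houwink relation in water ([η] = 0.0125 MW^0.78 mL/g,
# literature-derived); k_H ~ 0.4 is typical of flexible neutral polymers
peg_1mda = g.PolymerSpec("PEG 1 MDa", 1e6, 62.6,
                         intrinsic_viscosity=0.0125 * 1e6**0.78,
                         huggins_coefficient=0.4)

print(f"[η] = {peg_1mda.intrinsic_viscosity:.0f} mL/g")
print(f"{'cp (mg/mL)':>12}{'η/η_s':>10}{'D_P/D_W':>10}")
for cp in np.geomspace(0.05, 5.0, 8):
    eta = g.relative_viscosity(peg_1mda, cp)
    print(f"{cp:12.2f}{eta:10.2f}{g.particle_diffusivity_ratio(peg_1mda, cp):10.3f}")

print()
shear = 29.0  # 1/s, peristaltic shear in the small intestine
for lam in (0.009, 0.45):  # s, dilute polymer solution relaxation times
    wi = g.weissenberg_number(g.FlowContext(shear, lam))
    print(f"λ = {lam:5.3f} s  ->  Wi = {wi:5.2f}")
print("Wi spans ~0.3-10 across the relevant polymer sizes: elastic effects")
print("may matter in vivo, though the model here treats quiescent fluid.")
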