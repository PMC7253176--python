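"""Fit Hill dose-response curves to state occupancy vs ligand concentration.

Substrate (LTC4) binding populates the substrate-bound inward-facing state
IF1 (E = 0.80) with EC50 = 0.32 uM; ATP populates the outward-facing state
(E = 0.92) with EC50 = 0.05 mM.  This script generates noisy occupancy
points at those parameters and refits them with the Hill equation
occ(c) = floor + (ceiling - floor) * c / (EC50 + c).
"""

import numpy as np

import fretcycle as fc

for name, conc, ec50, floor, ceiling, unit in [
    ("LTC4 -> IF1 occupancy", np.geomspace(0.01, 30, 8), 0.32, 0.10, 0.50, "uM"),
    ("ATP  -> OF occupancy ", np.geomspace(0.005, 5, 8), 0.05, 0.10, 0.90, "mM"),
]:
    points = fc.simulate_occupancies(conc, ec50=ec50, n=1.0, floor=floor,
                                     ceiling=ceiling, sem=0.03, seed=1)
    fit = fc.fit_hill(points["concentration"], points["occupancy"],
                      points["sem"], fix_n=1.0)
    lo, hi = fit.ci()
    print(f"{name}: EC50 = {fit.ec50:.3f} {unit} "
          f"(generator {ec50} {unit}, 95% CI [{lo:.3f}, {hi:.3f}])")
# The generator EC50 lies inside the fit CI.  Note the breadth of the
# interval: a single 8-point titration determines EC50 only to tens of
# percent, which is why dose-response EC50s carry large quoted errors.
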