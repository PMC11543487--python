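"""Michaelis-Menten fitting and productivity under enzyme inactivation.

Simulates a 4-h NADH-depletion curve with the DES-medium kinetic constants
(v_max = 0.133 umol/mL/min, K_S = 12.133 umol/mL, c0 = 23.1 umol/mL),
refits the constants, then compares 10-day product formation in the DES
medium (enzyme half-life 29.9 days) and the reference buffer (2.1 days).
"""

import numpy as np

from descreen.kinetics import rate_from_half_life
from descreen.mm_productivity import (
    MMKinetics, ProductivityQuery, fit_mm, productivity_closed_form,
    simulate_depletion, volumetric_productivity,
)

schedule = np.arange(0.0, 241.0)
curve = simulate_depletion(MMKinetics(vmax=0.133, ks=12.133), 23.1, schedule)
fit = fit_mm(curve, 23.1)
print(f"recovered v_max = {fit.kinetics.vmax:.3f} umol/mL/min, "
      f"K_S = {fit.kinetics.ks:.3f} umol/mL")

for label, vmax, ks, t_half in (
    ("buffer        ", 0.091, 6.746, 2.1),
    ("20% DES buffer", 0.133, 12.133, 29.9),
):
    q = ProductivityQuery(
        kinetics=MMKinetics(vmax=vmax, ks=ks), substrate_conc=23.1,
        deactivation=rate_from_half_life(t_half), horizon=10.0,
    )
    print(f"{label}: 10-day product = {productivity_closed_form(q):7.1f} umol/mL")

print("batch volumetric productivity, 26.5 umol/mL over 4 h:",
      volumetric_productivity(26.5, 4.0), "umol/mL/h")

# The stabilized enzyme converts its kinetic advantage into a several-fold
# larger 10-day yield; the 4-h batch number reproduces the measured 6.6.
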