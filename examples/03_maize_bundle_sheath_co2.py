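"""Bundle-sheath CO2 in maize from the constant-conductance C4 balance.

Given one operating point (AN, Ci, Rdark) and the constant mesophyll and
bundle-sheath conductances, the CO2 mass balance across the bundle
sheath yields the mesophyll CO2 Cm, the PEP carboxylation rate Vp, the
bundle-sheath CO2 Cs and the leak rate.
"""

import numpy as np

from photolim import ACiCurve, estimate_cs, fit_aci_hyperbola, for_species, treatment_from_label

consts = for_species("maize")
AN, Ci, Rdark = 22.0, 230.0, 1.5

res = estimate_cs(AN, Ci, Rdark, consts)
print(f"Cm = {res.Cm:.1f} umol mol-1   Vp = {res.Vp:.1f} umol m-2 s-1")
print(f"Cs = {res.Cs:.0f} umol mol-1   leak = {res.leak:.1f} umol m-2 s-1")

# Cs >> Cm is the C4 CO2-concentrating mechanism at work: the PEP pump
# delivers more CO2 than Rubisco consumes and the surplus leaks back at
# rate gbs*(Cs - Cm).

# The AN-Ci response is summarised by a rectangular hyperbola, which can
# alternatively serve as the CO2-supply function:
ci = np.array([60.0, 100.0, 160.0, 250.0, 420.0, 800.0])
an = 45.0 * ci / (90.0 + ci)
curve = ACiCurve(treatment_from_label("maize", "control"), "demo",
                 tuple(zip(ci, an)))
fit = fit_aci_hyperbola(curve)
print(f"hyperbola fit: Amax = {fit.Amax:.1f}, K = {fit.K:.1f}, "
      f"rmse = {fit.rmse:.2g}")
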