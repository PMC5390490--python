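"""PSII operating efficiency and electron transport from fluorescence.

A steady-state fluorescence yield Fs and a saturating-pulse yield Fm'
give the PSII operating efficiency; with the incident light, the leaf
absorbance alpha and the PSII partitioning beta this becomes the linear
electron transport rate J.
"""

from photolim import electron_transport, phi_psii
from photolim.fluorescence import default_beta

Fs, Fm_prime = 0.25, 0.80
PPFD = 1500.0     # saturating light, umol photons m-2 s-1
alpha = 0.87      # measured leaf absorbance

phi = phi_psii(Fs, Fm_prime)
for species in ("rice", "maize"):
    beta = default_beta(species)
    J = electron_transport(phi, PPFD, alpha, beta)
    print(f"{species:6s}  PhiPSII = {phi:.4f}  beta = {beta}  "
          f"J = {J:.1f} umol e- m-2 s-1")

# PhiPSII is the fraction of absorbed PSII quanta driving electron
# transport; J differs between the species only through beta (0.5 for
# C3 leaves, 0.4 for maize).
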