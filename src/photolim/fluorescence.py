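"""PSII operating efficiency and linear electron transport rate.

The operating efficiency of photosystem II is obtained from steady-state
(Fs) and light-saturated-pulse (Fm') fluorescence yields,

    PhiPSII = (Fm' - Fs) / Fm'

and converted to a linear electron transport rate with the incident light,
the leaf absorbance alpha and the fraction beta of absorbed quanta reaching
PSII,

    J = PhiPSII * PPFD * alpha * beta.

beta is 0.5 for the C3 species and 0.4 for maize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import LeafRecord, Species, Treatment
from .errors import ValidationError

#: Default PSII partitioning fraction by photosynthetic type.
BETA_C3 = 0.5
BETA_C4 = 0.4


def default_beta(species_or_treatment: Species | Treatment | str) -> float:
    """beta for a species: 0.5 for C3 (rice, wheat), 0.4 for maize."""
    if isinstance(species_or_treatment, Treatment):
        species = species_or_treatment.species
    else:
        species = Species(species_or_treatment)
    return BETA_C4 if species.is_c4 else BETA_C3


@dataclass(frozen=True)
class FluorescenceResult:
    phi_psii: float  # dimensionless, 0-1
    J: float         # umol e- m-2 s-1


def phi_psii(Fs, Fm_prime):
    """PSII operating efficiency (Fm' - Fs)/Fm'.

    Scale-invariant: multiplying both yields by any c > 0 leaves the result
    unchanged. Accepts scalars or numpy arrays.
    """
    Fs = np.asarray(Fs, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm_prime <= 0):
        raise ValidationError("Fm_prime must be positive")
    if np.any(Fs < 0):
        raise ValidationError("Fs must be non-negative")
    if np.any(Fs > Fm_prime):
        raise ValidationError("Fs exceeds Fm_prime")
    out = (Fm_prime - Fs) / Fm_prime
    return float(out) if out.ndim == 0 else out


def electron_transport(phi, PPFD, alpha, beta):
    """Linear electron transport rate J = PhiPSII * PPFD * alpha * beta."""
    phi = np.asarray(phi, dtype=float)
    PPFD = np.asarray(PPFD, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValidationError("phi_psii must lie in [0, 1]")
    if np.any(PPFD < 0):
        raise ValidationError("PPFD must be >= 0")
    if np.any(alpha <= 0) or np.any(alpha > 1):
        raise ValidationError("alpha must lie in (0, 1]")
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise ValidationError("beta must lie in (0, 1)")
    out = phi * PPFD * alpha * beta
    return float(out) if out.ndim == 0 else out


def fluorescence_result(record: LeafRecord) -> FluorescenceResult:
    """PhiPSII and J for one leaf record."""
    phi = phi_psii(record.Fs, record.Fm_prime)
    j = electron_transport(phi, record.PPFD, record.alpha, record.beta)
    return FluorescenceResult(phi_psii=phi, J=j)
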