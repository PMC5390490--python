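"""C3 gas-exchange stages: gross assimilation, variable-J Cc and gm.

The mesophyll conductance of the C3 species (rice, wheat) is estimated with
the variable-J method: fluorescence-derived electron transport J and gas
exchange jointly determine the chloroplast CO2 mole fraction

    Cc = Gamma* (J + 8 (AN + Rd)) / (J - 4 (AN + Rd)),

the inversion of the RuBP-regeneration-limited assimilation rate
A = J (Cc - Gamma*)/(4 Cc + 8 Gamma*) - Rd. Mesophyll conductance then
follows from Fick's law, gm = AN / (Ci - Cc).

Rd here is the daytime mitochondrial respiration. Only pre-dawn dark
respiration is measured, so Rd defaults to Rdark/2, mirroring the
AG = AN + Rdark/2 convention for gross assimilation.

A forward FvCB model (Rubisco- and RuBP-regeneration-limited rates) is
exposed as the oracle for recovery tests and as the engine of the
synthetic-data generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import KineticConstants
from .errors import InfeasiblePointError, ValidationError

#: Fraction of pre-dawn dark respiration taken as daytime respiration.
RD_FRACTION = 0.5


@dataclass(frozen=True)
class C3DiffusionResult:
    """Variable-J outcome for one leaf."""

    AG: float    # gross assimilation, umol m-2 s-1
    gm: float    # mesophyll conductance to CO2, mol m-2 s-1
    Cc: float    # chloroplast CO2, umol mol-1
    feasible: bool = True


def gross_assimilation(AN: float, Rdark: float) -> float:
    """Gross assimilation AG = AN + Rdark/2, clipped at 0 for negative AN."""
    if Rdark < 0:
        raise ValidationError(f"Rdark must be >= 0, got {Rdark}")
    ag = AN + Rdark / 2.0
    if AN < 0:
        warnings.warn(
            f"negative AN ({AN}); gross assimilation clipped at 0",
            stacklevel=2,
        )
        ag = max(ag, 0.0)
    return ag


def cc_variable_j(AN: float, J: float, Rd: float, gamma_star: float) -> float:
    """Chloroplast CO2 from the variable-J inversion.

    Requires J > 4 (AN + Rd); otherwise the observation is incompatible
    with the electron-transport budget and an InfeasiblePointError is
    raised (the record should be flagged and excluded, not clipped).
    """
    if gamma_star <= 0:
        raise ValidationError("gamma_star must be positive")
    a = AN + Rd
    denom = J - 4.0 * a
    if denom <= 0:
        raise InfeasiblePointError(
            f"J ({J}) <= 4*(AN+Rd) ({4 * a}): variable-J denominator not positive"
        )
    return gamma_star * (J + 8.0 * a) / denom


def gm_from_cc(AN: float, Ci: float, Cc: float) -> float:
    """Mesophyll conductance gm = AN / (Ci - Cc)."""
    if Ci <= Cc:
        raise InfeasiblePointError(
            f"Ci ({Ci}) <= Cc ({Cc}): no CO2 gradient to sustain AN > 0"
        )
    if AN < 0:
        raise InfeasiblePointError("gm undefined for negative AN")
    return AN / (Ci - Cc)


def variable_j_result(
    AN: float,
    Ci: float,
    Rdark: float,
    J: float,
    constants: KineticConstants,
    rd_fraction: float = RD_FRACTION,
) -> C3DiffusionResult:
    """Full variable-J stage for one leaf; infeasible points are flagged."""
    ag = gross_assimilation(AN, Rdark)
    rd = rd_fraction * Rdark
    try:
        cc = cc_variable_j(AN, J, rd, constants.gamma_star)
        gm = gm_from_cc(AN, Ci, cc)
    except InfeasiblePointError:
        return C3DiffusionResult(AG=ag, gm=np.nan, Cc=np.nan, feasible=False)
    return C3DiffusionResult(AG=ag, gm=gm, Cc=cc)


def fvcb_forward(
    Cc: float,
    Vcmax: float,
    J: float,
    Rd: float,
    constants: KineticConstants,
) -> float:
    """Net assimilation from the FvCB model at known Cc.

    AN = min(Ac, Aj) - Rd with
    Ac = Vcmax (Cc - Gamma*) / (Cc + Kc (1 + O/Ko)) and
    Aj = J (Cc - Gamma*) / (4 Cc + 8 Gamma*).
    """
    if Cc <= 0:
        raise ValidationError(f"Cc must be positive, got {Cc}")
    gs_ = constants.gamma_star
    ac = Vcmax * (Cc - gs_) / (Cc + constants.Km)
    aj = J * (Cc - gs_) / (4.0 * Cc + 8.0 * gs_)
    return min(ac, aj) - Rd


def electron_use_j(AN: float, Rd: float, Cc: float, gamma_star: float) -> float:
    """Electron transport implied by the carboxylation/oxygenation budget.

    J = (AN + Rd)(4 Cc + 8 Gamma*)/(Cc - Gamma*); this is the J a
    fluorometer reports for a leaf operating at Cc, and is exactly what the
    variable-J inversion assumes. Used by the generator so that simulated
    fluorescence carries a recoverable ground truth.
    """
    if Cc <= gamma_star:
        raise InfeasiblePointError("Cc must exceed gamma_star for AN + Rd > 0")
    return (AN + Rd) * (4.0 * Cc + 8.0 * gamma_star) / (Cc - gamma_star)


def solve_c3_leaf(
    gs_co2: float,
    gm: float,
    Vcmax: float,
    Rd: float,
    Ca: float,
    constants: KineticConstants,
    J_potential: float | None = None,
) -> tuple[float, float, float]:
    """Steady-state (AN, Ci, Cc) for a leaf of known conductances.

    Balances CO2 supply through the stomata and mesophyll,
    AN = gs_co2 (Ca - Ci) = gm (Ci - Cc), against the FvCB demand at Cc.
    ``gs_co2`` is the stomatal conductance to CO2 (gs_H2O / 1.6). With
    ``J_potential`` of None the leaf is Rubisco-limited.
    """
    if min(gs_co2, gm, Vcmax, Ca) <= 0:
        raise ValidationError("gs_co2, gm, Vcmax, Ca must be positive")
    gtot = 1.0 / (1.0 / gs_co2 + 1.0 / gm)
    j = np.inf if J_potential is None else J_potential

    def residual(cc: float) -> float:
        demand = fvcb_forward(cc, Vcmax, j, Rd, constants)
        supply = gtot * (Ca - cc)
        return demand - supply

    # demand < supply near Gamma*, demand > supply near Ca: one root between
    lo = constants.gamma_star * 1.0001
    hi = Ca * 0.9999
    if residual(lo) * residual(hi) > 0:
        raise InfeasiblePointError(
            "no steady state: leaf cannot sustain positive assimilation"
        )
    cc = brentq(residual, lo, hi, xtol=1e-10, rtol=1e-14)
    an = fvcb_forward(cc, Vcmax, j, Rd, constants)
    ci = Ca - an / gs_co2
    return an, ci, cc
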