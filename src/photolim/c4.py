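"""Maize (C4) stages: hyperbolic AN-Ci fitting and bundle-sheath CO2.

Maize concentrates CO2 into the bundle sheath; both the mesophyll
conductance gm and the bundle-sheath conductance gbs are treated as
constants. The bundle-sheath CO2 mole fraction Cs follows from a
CO2 mass balance across the bundle-sheath interface:

    Cm = Ci - AN / gm                     (mesophyll CO2)
    Vp = Vpmax Cm / (Cm + Kp)             (PEP carboxylation supply)
    Rm = Rm_fraction * Rdark              (mesophyll respiration)
    Cs = Cm + (Vp - AN - Rm) / gbs        (leak balance)

so that the leak rate gbs (Cs - Cm) equals the overpumping Vp - AN - Rm.
The AN-Ci response is summarised by a rectangular hyperbola
AN = Amax Ci / (K + Ci), which can alternatively supply Vp at the
operating Cm (config switch ``vp_source``).

Biochemical limitation analysis in maize is restricted to the C3 cycle:
the Rubisco-limited rate evaluated at Cs (``c4_forward``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .constants import KineticConstants
from .datamodel import ACiCurve
from .errors import FitError, InfeasiblePointError, ValidationError


@dataclass(frozen=True)
class HyperbolaFit:
    """Least-squares fit of AN = Amax * Ci / (K + Ci)."""

    Amax: float   # umol m-2 s-1
    K: float      # umol mol-1
    rmse: float   # umol m-2 s-1
    degenerate: bool = False  # K at the boundary (flat plateau)

    def predict(self, ci):
        ci = np.asarray(ci, dtype=float)
        out = self.Amax * ci / (self.K + ci)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class C4Result:
    Cm: float     # mesophyll CO2, umol mol-1
    Vp: float     # PEP carboxylation rate, umol m-2 s-1
    Cs: float     # bundle-sheath CO2, umol mol-1
    leak: float   # bundle-sheath leak rate gbs*(Cs-Cm), umol m-2 s-1
    feasible: bool = True


_K_FLOOR = 1e-6  # boundary below which the hyperbola is a flat plateau


def fit_aci_hyperbola(curve: ACiCurve) -> HyperbolaFit:
    """Fit the rectangular hyperbola to an AN-Ci curve.

    A plateau-like curve drives K to its lower boundary; the fit is then
    returned with ``degenerate=True`` rather than failing, since Amax is
    still well determined.
    """
    ci = np.asarray(curve.ci, dtype=float)
    an = np.asarray(curve.an, dtype=float)

    def hyperbola(c, amax, k):
        return amax * c / (k + c)

    amax0 = max(float(an.max()), 1e-3) * 1.2
    k0 = float(np.median(ci))
    try:
        popt, _ = curve_fit(
            hyperbola,
            ci,
            an,
            p0=(amax0, k0),
            bounds=((1e-9, _K_FLOOR), (np.inf, np.inf)),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(f"A-Ci hyperbola fit did not converge: {exc}") from exc
    amax, k = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((hyperbola(ci, amax, k) - an) ** 2)))
    # K far below the smallest observed Ci means the curve is already a
    # flat plateau over the measured range: the half-saturation point is
    # unidentified
    degenerate = k < 0.01 * float(ci.min())
    return HyperbolaFit(Amax=amax, K=k, rmse=rmse, degenerate=degenerate)


def estimate_cs(
    AN: float,
    Ci: float,
    Rdark: float,
    constants: KineticConstants,
    vp_source: str = "michaelis",
    hyperbola: HyperbolaFit | None = None,
) -> C4Result:
    """Bundle-sheath CO2 from the constant-conductance mass balance.

    ``vp_source='michaelis'`` computes the PEP carboxylation rate from the
    shipped Vpmax/Kp kinetics; ``'hyperbola'`` evaluates the fitted AN-Ci
    hyperbola at the operating Cm as the supply rate instead.
    """
    cm = Ci - AN / constants.gm_c4
    if cm <= 0:
        return C4Result(Cm=cm, Vp=np.nan, Cs=np.nan, leak=np.nan, feasible=False)
    if vp_source == "michaelis":
        vp = cm * constants.Vpmax / (cm + constants.Kp)
    elif vp_source == "hyperbola":
        if hyperbola is None:
            raise ValidationError("vp_source='hyperbola' requires a HyperbolaFit")
        vp = hyperbola.predict(cm)
    else:
        raise ValidationError(f"unknown vp_source {vp_source!r}")
    rm = constants.Rm_fraction * Rdark
    cs = cm + (vp - AN - rm) / constants.gbs
    leak = constants.gbs * (cs - cm)
    if cs <= 0:
        return C4Result(Cm=cm, Vp=vp, Cs=cs, leak=leak, feasible=False)
    return C4Result(Cm=cm, Vp=vp, Cs=cs, leak=leak)


def c4_forward(
    Cs: float,
    Vcmax: float,
    Rd: float,
    constants: KineticConstants,
) -> float:
    """Rubisco-limited (C3-cycle) net assimilation at bundle-sheath CO2 Cs."""
    if Cs <= 0:
        raise ValidationError(f"Cs must be positive, got {Cs}")
    return Vcmax * (Cs - constants.gamma_star) / (Cs + constants.Km) - Rd


def solve_c4_leaf(
    gs_co2: float,
    Vcmax: float,
    Rd: float,
    Ca: float,
    constants: KineticConstants,
) -> tuple[float, float, float, float]:
    """Steady-state (AN, Ci, Cm, Cs) for a maize leaf.

    Couples stomatal supply AN = gs_co2 (Ca - Ci), the constant-gm
    mesophyll gradient, the PEP carboxylation pump and the Rubisco-limited
    C3-cycle demand at Cs. Root-found on AN.
    """
    if min(gs_co2, Vcmax, Ca) <= 0:
        raise ValidationError("gs_co2, Vcmax, Ca must be positive")
    # Rd is daytime respiration (= Rdark/2); Rm is defined on Rdark.
    rdark = 2.0 * Rd

    def states(an: float) -> tuple[float, float, float]:
        ci = Ca - an / gs_co2
        cm = ci - an / constants.gm_c4
        vp = cm * constants.Vpmax / (cm + constants.Kp)
        cs = cm + (vp - an - constants.Rm_fraction * rdark) / constants.gbs
        return ci, cm, cs

    def residual(an: float) -> float:
        _, cm, cs = states(an)
        if cm <= 0 or cs <= constants.gamma_star:
            return -1e6  # infeasible branch: force root search lower
        return c4_forward(cs, Vcmax, Rd, constants) - an

    lo, hi = -Rd, min(Vcmax, gs_co2 * Ca) * 0.9999
    if residual(lo) < 0:
        raise InfeasiblePointError("maize leaf infeasible at AN = -Rd")
    if residual(hi) > 0:
        raise InfeasiblePointError("no steady state below the supply ceiling")
    an = brentq(residual, lo, hi, xtol=1e-10, rtol=1e-14)
    ci, cm, cs = states(an)
    return an, ci, cm, cs
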