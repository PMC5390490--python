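"""Domain types for leaf-level gas exchange, fluorescence and biochemistry.

All quantities are kept in the units they are measured in:

* assimilation and respiration rates in umol CO2 m-2 s-1,
* conductances in mol m-2 s-1 (gs to water vapour; gm, gbs to CO2),
* CO2 mole fractions in umol mol-1,
* PPFD in umol photons m-2 s-1,
* biochemical activities in umol CO2 mg-1 TSP min-1.

No unit conversion happens at I/O time; the single gs H2O -> CO2 conversion
(divide by 1.6) is applied inside the limitation analysis where it is needed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ValidationError


class Species(str, enum.Enum):
    RICE = "rice"
    WHEAT = "wheat"
    MAIZE = "maize"

    @property
    def is_c4(self) -> bool:
        return self is Species.MAIZE


class Irrigation(str, enum.Enum):
    WW = "WW"  # well-watered, 100% field capacity
    WD = "WD"  # moderate water deficit, 45% field capacity


class GrowthTemperature(str, enum.Enum):
    CONTROL25 = "control25"  # 25/20 C day/night
    HT38 = "HT38"            # 38/33 C day/night


#: Treatment labels as used in the experimental design.
_TREATMENT_LABELS = {
    (Irrigation.WW, GrowthTemperature.CONTROL25): "control",
    (Irrigation.WD, GrowthTemperature.CONTROL25): "WD",
    (Irrigation.WW, GrowthTemperature.HT38): "HT",
    (Irrigation.WD, GrowthTemperature.HT38): "HT-WD",
}


@dataclass(frozen=True, order=True)
class Treatment:
    """One cell of the species x irrigation x growth-temperature factorial."""

    species: Species
    irrigation: Irrigation
    temperature: GrowthTemperature

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        object.__setattr__(self, "irrigation", Irrigation(self.irrigation))
        object.__setattr__(
            self, "temperature", GrowthTemperature(self.temperature)
        )

    @property
    def label(self) -> str:
        """'control', 'WD', 'HT' or 'HT-WD'."""
        return _TREATMENT_LABELS[(self.irrigation, self.temperature)]

    @property
    def is_c4(self) -> bool:
        return self.species.is_c4

    @property
    def is_control(self) -> bool:
        return (
            self.irrigation is Irrigation.WW
            and self.temperature is GrowthTemperature.CONTROL25
        )

    def control(self) -> "Treatment":
        """The reference (well-watered, control-temperature) treatment."""
        return Treatment(
            self.species, Irrigation.WW, GrowthTemperature.CONTROL25
        )


def treatment_from_label(species: Species | str, label: str) -> Treatment:
    """Build a Treatment from a 'control'/'WD'/'HT'/'HT-WD' label."""
    for (irr, temp), lab in _TREATMENT_LABELS.items():
        if lab == label:
            return Treatment(Species(species), irr, temp)
    raise ValidationError(f"unknown treatment label {label!r}")


@dataclass(frozen=True)
class LeafRecord:
    """One leaf's steady-state gas exchange + fluorescence observation.

    ``alpha`` is the measured leaf absorbance and ``beta`` the partitioning
    of absorbed quanta to photosystem II (0.5 for the C3 species, 0.4 for
    maize unless overridden per record).
    """

    treatment: Treatment
    replicate_id: str
    AN: float          # net CO2 assimilation, umol m-2 s-1
    gs: float          # stomatal conductance to H2O, mol m-2 s-1
    Ci: float          # substomatal CO2, umol mol-1
    Ca: float          # ambient CO2, umol mol-1
    PPFD: float        # umol photons m-2 s-1
    Tleaf: float       # leaf temperature, C
    Rdark: float       # pre-dawn dark respiration, umol m-2 s-1 (>= 0)
    Fs: float          # steady-state fluorescence yield
    Fm_prime: float    # light-adapted maximal fluorescence yield
    alpha: float       # leaf absorbance, 0-1
    beta: float        # PSII partitioning fraction, 0-1

    def __post_init__(self) -> None:
        if not self.Fs > 0:
            raise ValidationError(f"Fs must be positive, got {self.Fs}")
        if self.Fm_prime < self.Fs:
            raise ValidationError(
                f"Fm_prime ({self.Fm_prime}) < Fs ({self.Fs})"
            )
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.beta < 1:
            raise ValidationError(f"beta must be in (0, 1), got {self.beta}")
        if self.Rdark < 0:
            raise ValidationError(f"Rdark must be >= 0, got {self.Rdark}")
        if self.gs < 0:
            raise ValidationError(f"gs must be >= 0, got {self.gs}")
        if self.PPFD < 0:
            raise ValidationError(f"PPFD must be >= 0, got {self.PPFD}")
        if self.AN > 0 and self.Ci > self.Ca:
            raise ValidationError(
                f"Ci ({self.Ci}) > Ca ({self.Ca}) with positive AN"
            )


@dataclass(frozen=True)
class ACiCurve:
    """An AN-Ci response curve for the C4 model inversion.

    At least 4 points are required (the hyperbola has 2 parameters) and Ci
    must be strictly increasing.
    """

    treatment: Treatment
    replicate_id: str
    points: tuple[tuple[float, float], ...]  # (Ci, AN) pairs

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(a)) for c, a in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 4:
            raise ValidationError(
                f"A-Ci curve needs >= 4 points, got {len(pts)}"
            )
        cis = [c for c, _ in pts]
        if any(b <= a for a, b in zip(cis, cis[1:])):
            raise ValidationError("Ci values must be strictly increasing")

    @property
    def ci(self) -> tuple[float, ...]:
        return tuple(c for c, _ in self.points)

    @property
    def an(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.points)


@dataclass(frozen=True)
class BiochemRecord:
    """Rubisco activities, amounts and Rca band intensities for one sample.

    Activities are per mg of total soluble protein (TSP); Rca quantities are
    relative to the control treatment of the same species (control = 1).
    ``activity_slack`` absorbs assay noise in the total >= initial check.
    """

    treatment: Treatment
    replicate_id: str
    initial_activity: float   # umol CO2 mg-1 TSP min-1
    total_activity: float     # umol CO2 mg-1 TSP min-1
    rubisco_amount: float     # mg Rubisco mg-1 TSP
    rca_total: float = 1.0    # relative to control
    rca_large: float = 0.0    # relative to control (absent in maize)
    rca_small: float = 1.0    # relative to control
    tsp_conc: float | None = None  # mg mL-1, for raw-count workflows
    activity_slack: float = field(default=0.05, compare=False)

    def __post_init__(self) -> None:
        for name in (
            "initial_activity", "total_activity", "rubisco_amount",
            "rca_total", "rca_large", "rca_small",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.total_activity * (1 + self.activity_slack) < self.initial_activity:
            raise ValidationError(
                f"initial activity ({self.initial_activity}) exceeds total "
                f"({self.total_activity}) beyond the {self.activity_slack:.0%}"
                " noise slack"
            )
        if self.tsp_conc is not None and self.tsp_conc <= 0:
            raise ValidationError("tsp_conc must be positive when given")


@dataclass(frozen=True)
class LimitationResult:
    """Partition of the photosynthetic decline relative to a reference.

    SL, MCL, BL are the stomatal, mesophyll and biochemical components of
    the (log-scale) gross-assimilation decline; DL = SL + MCL is the total
    diffusive component. ``*_frac`` are the same components normalised to
    sum to 1 (shares of the total limitation).
    """

    treatment: Treatment
    reference: Treatment
    SL: float
    MCL: float
    BL: float
    SL_frac: float = float("nan")
    MCL_frac: float = float("nan")
    BL_frac: float = float("nan")

    @property
    def DL(self) -> float:
        """Diffusive limitation, SL + MCL by definition."""
        return self.SL + self.MCL

    @property
    def total(self) -> float:
        return self.SL + self.MCL + self.BL
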