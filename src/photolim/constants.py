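"""Kinetic and protocol constants with explicit provenance.

The study measures everything at 25 C, so no temperature corrections are
applied anywhere in the package. Rubisco carboxylase turnover rates (kcat)
were measured in vitro at 25 C for each species; the Michaelis constants,
the CO2 compensation point Gamma*, and the C4 transport parameters are
standard 25 C literature values and are flagged as such so that every run
manifest can state exactly which numbers entered the analysis.

Provenance flags
----------------
``study``              printed in the experimental study this pipeline reproduces
``literature-default`` standard value shipped with the package
``user``               supplied via a config override
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .datamodel import Species
from .errors import ValidationError

#: Species-specific Rubisco carboxylase turnover rates at 25 C (s-1 per site).
KCAT_BY_SPECIES = {
    Species.RICE: 2.1,
    Species.WHEAT: 2.2,
    Species.MAIZE: 4.1,
}


@dataclass(frozen=True)
class KineticConstants:
    """Model constants for one species, all at 25 C.

    Units: gamma_star, Kc, Kp in umol mol-1; Ko, O in mmol mol-1;
    kcat in s-1; conductances in mol m-2 s-1; Vpmax in umol m-2 s-1;
    rubisco_molar_mass in g mol-1 (holoenzyme).
    """

    species: Species
    gamma_star: float = 42.75     # CO2 compensation point without Rd
    Kc: float = 404.9             # Rubisco Michaelis constant for CO2
    Ko: float = 278.4             # Rubisco Michaelis constant for O2
    O: float = 210.0              # chloroplast O2 mole fraction
    kcat: float = float("nan")    # set per species in for_species()
    gbs: float = 0.01             # bundle-sheath conductance (C4)
    gm_c4: float = 1.0            # constant mesophyll conductance (C4)
    Vpmax: float = 120.0          # maximal PEP carboxylation rate (C4)
    Kp: float = 80.0              # PEPC Michaelis constant for CO2 (C4)
    Rm_fraction: float = 0.5      # mesophyll share of dark respiration (C4)
    rubisco_molar_mass: float = 550_000.0  # g mol-1, L8S8 holoenzyme
    sites_per_holoenzyme: int = 8
    provenance: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        for f in fields(self):
            if f.name in ("species", "provenance"):
                continue
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(
                    f"constant {f.name} must be strictly positive, got {v}"
                )

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc * (1 + O/Ko), umol mol-1."""
        return self.Kc * (1.0 + self.O / self.Ko)


_DEFAULT_PROVENANCE = {
    "gamma_star": "literature-default",
    "Kc": "literature-default",
    "Ko": "literature-default",
    "O": "literature-default",
    "kcat": "study",
    "gbs": "literature-default",
    "gm_c4": "literature-default",
    "Vpmax": "literature-default",
    "Kp": "literature-default",
    "Rm_fraction": "literature-default",
    "rubisco_molar_mass": "literature-default",
    "sites_per_holoenzyme": "literature-default",
}


def for_species(
    species: Species | str,
    overrides: Mapping[str, Any] | None = None,
) -> KineticConstants:
    """Constants for one species: defaults, then user overrides.

    Every constant carries exactly one provenance flag; overrides are
    re-flagged ``user``.
    """
    species = Species(species)
    prov = dict(_DEFAULT_PROVENANCE)
    consts = KineticConstants(species=species, kcat=KCAT_BY_SPECIES[species])
    if overrides:
        unknown = set(overrides) - set(prov)
        if unknown:
            raise ValidationError(f"unknown constant overrides: {sorted(unknown)}")
        consts = replace(consts, **{k: float(v) for k, v in overrides.items()})
        for k in overrides:
            prov[k] = "user"
    return replace(consts, provenance=prov)


def load_constants(
    path: str | Path | None,
    species: Species | str,
) -> KineticConstants:
    """Load constants for a species from a YAML config file.

    The file may contain a top-level ``constants:`` mapping, optionally with
    per-species sub-mappings (keys 'rice'/'wheat'/'maize') that win over the
    shared entries. ``path=None`` returns pure defaults.
    """
    species = Species(species)
    if path is None:
        return for_species(species)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    section = cfg.get("constants", cfg) or {}
    overrides: dict[str, Any] = {
        k: v for k, v in section.items()
        if k not in (s.value for s in Species) and not isinstance(v, dict)
    }
    per_species = section.get(species.value) or {}
    overrides.update(per_species)
    return for_species(species, overrides)
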