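"""Synthetic factorial experiments with recoverable ground truth.

The generator emulates the study design — rice, wheat and maize under
control, water deficit (WD), high growth temperature (HT) and the combined
HT-WD treatment, 4-5 replicates each — so that every analysis stage can be
exercised, and inverted, without any measured data.

Physiological coherence is enforced by construction:

* Biochemistry comes first: Rubisco amount and activation state are
  sampled per replicate, and Vcmax is their biochemical product, so the
  gas exchange and the biochemistry of a replicate agree.
* C3 leaves are solved through the forward FvCB model at the sampled
  gs/gm/Vcmax (Rubisco-limited), maize leaves through the C4
  bundle-sheath balance, so the inverse pipeline has an exact target.
* Fluorescence is generated backwards: the electron transport implied by
  the leaf's fluxes fixes PhiPSII, Fm' is drawn in [0.5, 0.8] and Fs is
  solved so the fluorescence stage reproduces the generating J.

Treatment effects are multiplicative on the control means; WD scenarios
must reduce gs to <= 60% of the well-watered mean (the study's >= 40%
stomatal-closure criterion for declaring water deficit). Noise is
log-normal (multiplicative, positivity-preserving), truncated at 3 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import c3, c4
from .biochem import VcmaxInput, rubisco_area_density, vcmax_biochemical
from .constants import KineticConstants, for_species
from .datamodel import (
    ACiCurve,
    BiochemRecord,
    LeafRecord,
    Species,
    Treatment,
    treatment_from_label,
)
from .errors import GenerationError, ValidationError
from .fluorescence import default_beta
from .limitations import GS_H2O_TO_CO2

TREATMENT_LABELS = ("control", "WD", "HT", "HT-WD")

#: Parameters a treatment multiplier may act on.
_MULT_PARAMS = (
    "gs", "gm", "Rdark", "rubisco_amount", "activation_state",
    "total_activity", "rca_total", "rca_large", "rca_small",
)


@dataclass(frozen=True)
class SpeciesBaseline:
    """Control-treatment means for one species.

    Rubisco amount and activities are the control values printed for the
    study (per mg TSP); gs, gm and Rdark are typical glasshouse values for
    these crops measured at 25 C, saturating light and Ca = 400.
    """

    gs: float                  # mol H2O m-2 s-1
    Rdark: float               # umol CO2 m-2 s-1
    rubisco_amount: float      # mg Rubisco mg-1 TSP
    total_activity: float      # umol CO2 mg-1 TSP min-1
    activation_state: float    # fraction
    gm: float | None = None    # mol CO2 m-2 s-1 (C3 only)
    rca_total: float = 1.0     # relative to control
    rca_large: float = 1.0
    rca_small: float = 1.0
    tsp_per_area: float = 5.0  # g TSP m-2 leaf
    tsp_conc: float = 10.0     # mg mL-1 in the crude extract


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario: per-species baselines, treatment multipliers, noise."""

    baselines: dict[Species, SpeciesBaseline]
    multipliers: dict[str, dict[str, dict[Species, float]]]
    cv: dict[str, float] = field(default_factory=dict)
    replicates: int = 5
    Ca: float = 400.0      # umol mol-1
    PPFD: float = 1500.0   # umol m-2 s-1
    alpha: float = 0.87    # leaf absorbance
    Tleaf: float = 25.0
    aci_ca_grid: tuple[float, ...] = (
        100.0, 150.0, 250.0, 400.0, 600.0, 900.0, 1300.0, 1800.0
    )
    aci_noise_sd: float = 0.0  # umol m-2 s-1, additive on curve AN

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("need >= 2 replicates")
        for label in ("WD", "HT-WD"):
            for sp in self.baselines:
                m = self.multiplier(label, "gs", sp)
                if m > 0.60:
                    raise ValidationError(
                        f"{label}/{sp.value}: gs multiplier {m} violates the "
                        ">= 40% stomatal-closure water-deficit criterion"
                    )
        for p, v in self.cv.items():
            if v < 0:
                raise ValidationError(f"CV for {p} must be >= 0")

    def multiplier(self, label: str, param: str, species: Species) -> float:
        entry = self.multipliers.get(label, {}).get(param, 1.0)
        if isinstance(entry, dict):
            return float(entry.get(species, 1.0))
        return float(entry)

    def cv_for(self, param: str) -> float:
        return float(self.cv.get(param, 0.0))


_DEFAULT_CV = {
    "gs": 0.10, "gm": 0.10, "Rdark": 0.10,
    "rubisco_amount": 0.10, "activation_state": 0.05,
    "total_activity": 0.10,
    "rca_total": 0.10, "rca_large": 0.12, "rca_small": 0.12,
}


def default_study_config(
    replicates: int = 5,
    noise: bool = True,
) -> ScenarioConfig:
    """The study-like scenario.

    Control biochemistry means are the printed control values (Rubisco
    amount 0.49/0.34/0.15 mg mg-1 TSP; initial activity 0.31/0.19/0.08 and
    total activity 0.36/0.44/0.13 umol CO2 mg-1 TSP min-1 for rice, wheat,
    maize; activation state = initial/total). Treatment multipliers encode
    the qualitative pattern: WD halves gs (C3 gm down in rice only,
    Rubisco amount down in rice and maize, maize activation up); HT halves
    the activation state in all species and lowers Rubisco amount in rice;
    HT-WD combines both, hitting rice hardest.
    """
    rice, wheat, maize = Species.RICE, Species.WHEAT, Species.MAIZE
    baselines = {
        rice: SpeciesBaseline(
            gs=0.35, gm=0.30, Rdark=1.5,
            rubisco_amount=0.49, total_activity=0.36,
            activation_state=0.31 / 0.36,
        ),
        wheat: SpeciesBaseline(
            gs=0.30, gm=0.25, Rdark=1.4,
            rubisco_amount=0.34, total_activity=0.44,
            activation_state=0.19 / 0.44,
        ),
        maize: SpeciesBaseline(
            gs=0.20, Rdark=1.5,
            rubisco_amount=0.15, total_activity=0.13,
            activation_state=0.08 / 0.13,
            rca_large=0.0,  # maize lacks the redox-sensitive large isoform
        ),
    }
    multipliers = {
        "control": {},
        "WD": {
            "gs": {rice: 0.5, wheat: 0.5, maize: 0.5},
            "gm": {rice: 0.7, wheat: 1.0},
            "rubisco_amount": {rice: 0.8, wheat: 1.0, maize: 0.75},
            "activation_state": {rice: 0.95, wheat: 1.0, maize: 1.1},
            "rca_total": {rice: 1.0, wheat: 1.0, maize: 1.1},
        },
        "HT": {
            "gs": {rice: 1.0, wheat: 1.0, maize: 1.0},
            "gm": {rice: 0.8, wheat: 1.0},
            "rubisco_amount": {rice: 0.7, wheat: 1.0, maize: 1.0},
            "activation_state": {rice: 0.5, wheat: 0.5, maize: 0.5},
            "rca_large": {rice: 1.1, wheat: 0.8},
        },
        "HT-WD": {
            "gs": {rice: 0.5, wheat: 0.5, maize: 0.5},
            "gm": {rice: 0.56, wheat: 1.0},
            "rubisco_amount": {rice: 0.5, wheat: 1.0, maize: 0.7},
            "activation_state": {rice: 0.45, wheat: 0.5, maize: 0.5},
            "total_activity": {rice: 0.8, wheat: 1.0, maize: 1.0},
            "rca_total": {wheat: 1.3},
            "rca_small": {wheat: 1.4},
        },
    }
    return ScenarioConfig(
        baselines=baselines,
        multipliers=multipliers,
        cv=dict(_DEFAULT_CV) if noise else {},
        replicates=replicates,
    )


@dataclass(frozen=True)
class SimulatedExperiment:
    leaf_records: list[LeafRecord]
    aci_curves: list[ACiCurve]
    biochem_records: list[BiochemRecord]
    ground_truth: pd.DataFrame


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-preserving log-normal draw, truncated at +-3 sigma."""
    if cv == 0 or mean == 0:
        return mean
    sigma = float(np.sqrt(np.log1p(cv**2)))
    z = float(rng.standard_normal())
    z = float(np.clip(z, -3.0, 3.0))
    return mean * float(np.exp(sigma * z - 0.5 * sigma**2))


def _fluorescence_backwards(
    rng: np.random.Generator,
    J: float,
    PPFD: float,
    alpha: float,
    beta: float,
    scenario: str,
) -> tuple[float, float]:
    """Pick (Fs, Fm') so that the fluorescence stage reproduces J."""
    phi = J / (PPFD * alpha * beta)
    if not 0 <= phi <= 1:
        raise GenerationError(
            f"{scenario}: implied PhiPSII {phi:.3f} outside [0, 1]; "
            "scenario is infeasible at this light level"
        )
    fm_prime = float(rng.uniform(0.5, 0.8))
    fs = fm_prime * (1.0 - phi)
    return fs, fm_prime


def generate_experiment(
    config: ScenarioConfig,
    seed: int,
    constants: dict[Species, KineticConstants] | None = None,
) -> SimulatedExperiment:
    """One complete synthetic experiment (deterministic in seed+config)."""
    rng = np.random.default_rng(seed)
    constants = constants or {sp: for_species(sp) for sp in config.baselines}
    leaves: list[LeafRecord] = []
    curves: list[ACiCurve] = []
    biochem: list[BiochemRecord] = []
    truth_rows: list[dict] = []

    for species in sorted(config.baselines, key=lambda s: s.value):
        base = config.baselines[species]
        consts = constants[species]
        beta = default_beta(species)
        for label in TREATMENT_LABELS:
            treatment = treatment_from_label(species, label)
            scenario = f"{species.value}/{label}"

            def mean(param: str, base_value: float) -> float:
                return base_value * config.multiplier(label, param, species)

            for rep in range(1, config.replicates + 1):
                rid = f"r{rep}"
                gs = _lognormal(rng, mean("gs", base.gs), config.cv_for("gs"))
                rdark = _lognormal(
                    rng, mean("Rdark", base.Rdark), config.cv_for("Rdark")
                )
                amount = _lognormal(
                    rng,
                    mean("rubisco_amount", base.rubisco_amount),
                    config.cv_for("rubisco_amount"),
                )
                act = _lognormal(
                    rng,
                    mean("activation_state", base.activation_state),
                    config.cv_for("activation_state"),
                )
                act = min(act, 1.0)
                total_act = _lognormal(
                    rng,
                    mean("total_activity", base.total_activity),
                    config.cv_for("total_activity"),
                )
                rca = {
                    p: _lognormal(
                        rng, mean(p, getattr(base, p)), config.cv_for(p)
                    )
                    for p in ("rca_total", "rca_large", "rca_small")
                }
                vcmax = vcmax_biochemical(
                    VcmaxInput(
                        rubisco_area_density=rubisco_area_density(
                            amount, base.tsp_per_area
                        ),
                        activation_state=act,
                        kcat=consts.kcat,
                        molar_mass=consts.rubisco_molar_mass,
                        sites=consts.sites_per_holoenzyme,
                    )
                )
                rd = c3.RD_FRACTION * rdark
                gs_co2 = gs / GS_H2O_TO_CO2
                truth = {
                    "species": species.value,
                    "treatment": label,
                    "replicate_id": rid,
                    "gs": gs,
                    "gs_co2": gs_co2,
                    "Rdark": rdark,
                    "Rd": rd,
                    "Vcmax": vcmax,
                    "rubisco_amount": amount,
                    "activation_state": act,
                    "total_activity": total_act,
                    "tsp_per_area": base.tsp_per_area,
                }

                if species.is_c4:
                    try:
                        an, ci, cm, cs = c4.solve_c4_leaf(
                            gs_co2, vcmax, rd, config.Ca, consts
                        )
                    except Exception as exc:
                        raise GenerationError(
                            f"{scenario}: maize leaf infeasible ({exc})"
                        ) from exc
                    # C4 electron demand: ~6 e- per net CO2 (C3 cycle +
                    # PEP regeneration ATP surcharge)
                    j = 6.0 * (an + rd)
                    truth.update(
                        {"gm": consts.gm_c4, "AN": an, "Ci": ci,
                         "Cm": cm, "Cs": cs, "Cc": np.nan, "J": j}
                    )
                    curves.append(
                        _aci_curve(
                            rng, treatment, rid, gs_co2, vcmax, rd,
                            consts, config,
                        )
                    )
                else:
                    gm = _lognormal(
                        rng, mean("gm", base.gm), config.cv_for("gm")
                    )
                    try:
                        an, ci, cc = c3.solve_c3_leaf(
                            gs_co2, gm, vcmax, rd, config.Ca, consts
                        )
                    except Exception as exc:
                        raise GenerationError(
                            f"{scenario}: C3 leaf infeasible ({exc})"
                        ) from exc
                    j = c3.electron_use_j(an, rd, cc, consts.gamma_star)
                    truth.update(
                        {"gm": gm, "AN": an, "Ci": ci, "Cc": cc,
                         "Cm": np.nan, "Cs": np.nan, "J": j}
                    )

                fs, fm_prime = _fluorescence_backwards(
                    rng, j, config.PPFD, config.alpha, beta, scenario
                )
                truth["AG"] = an + rdark / 2.0
                leaves.append(
                    LeafRecord(
                        treatment=treatment,
                        replicate_id=rid,
                        AN=an, gs=gs, Ci=ci, Ca=config.Ca,
                        PPFD=config.PPFD, Tleaf=config.Tleaf, Rdark=rdark,
                        Fs=fs, Fm_prime=fm_prime,
                        alpha=config.alpha, beta=beta,
                    )
                )
                biochem.append(
                    BiochemRecord(
                        treatment=treatment,
                        replicate_id=rid,
                        initial_activity=act * total_act,
                        total_activity=total_act,
                        rubisco_amount=amount,
                        rca_total=rca["rca_total"],
                        rca_large=rca["rca_large"],
                        rca_small=rca["rca_small"],
                        tsp_conc=base.tsp_conc,
                    )
                )
                truth_rows.append(truth)

    return SimulatedExperiment(
        leaf_records=leaves,
        aci_curves=curves,
        biochem_records=biochem,
        ground_truth=pd.DataFrame(truth_rows),
    )


def _aci_curve(
    rng: np.random.Generator,
    treatment: Treatment,
    replicate_id: str,
    gs_co2: float,
    vcmax: float,
    rd: float,
    consts: KineticConstants,
    config: ScenarioConfig,
) -> ACiCurve:
    """Simulate an AN-Ci response by sweeping chamber CO2."""
    points = []
    for ca in config.aci_ca_grid:
        try:
            an, ci, _, _ = c4.solve_c4_leaf(gs_co2, vcmax, rd, ca, consts)
        except Exception:
            continue  # low-Ca points may be infeasible; skip them
        if config.aci_noise_sd > 0:
            an += float(rng.normal(0.0, config.aci_noise_sd))
        points.append((ci, an))
    if len(points) < 4:
        raise GenerationError(
            f"{treatment.species.value}/{treatment.label}: fewer than 4 "
            "feasible A-Ci points"
        )
    return ACiCurve(
        treatment=treatment, replicate_id=replicate_id, points=tuple(points)
    )
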