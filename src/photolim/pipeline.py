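"""End-to-end orchestration: records in, limitation tables and stats out.

Stages (each also exposed on its own for the CLI):

1. fluorescence  — PhiPSII and J per leaf
2. c3            — variable-J Cc and gm for rice and wheat
3. c4            — A-Ci hyperbola fits and bundle-sheath Cs for maize
4. biochem       — activation state and biochemical Vcmax per sample
5. limitations   — control-referenced decomposition with bootstrap SEs
6. stats         — factorial ANOVA, Duncan letters, trait regressions

Outputs are CSVs plus a deterministic ``manifest.json`` recording the
config hash, the seed, every constant's provenance and all warnings, so a
re-run with the same inputs reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, c3, c4
from .biochem import VcmaxInput, activation_state, rubisco_area_density, vcmax_biochemical
from .constants import for_species
from .datamodel import Species
from .errors import PhotolimError
from .fluorescence import electron_transport, phi_psii
from .io import (
    biochem_records_frame,
    leaf_records_frame,
    read_aci_curves,
    read_biochem_records,
    read_leaf_records,
    write_aci_curves,
    write_biochem_records,
    write_leaf_records,
)
from .limitations import GS_H2O_TO_CO2, bootstrap_partition
from .simulate import default_study_config, generate_experiment
from .stats import duncan_test, factorial_anova, simple_regression

log = logging.getLogger("photolim")

DEFAULT_CONFIG: dict[str, Any] = {
    "column_maps": {},
    "constants": {},
    "tsp_per_area": 5.0,     # g TSP m-2; bridges per-TSP biochem to leaf area
    "rd_fraction": 0.5,      # daytime Rd as a fraction of Rdark
    "vp_source": "michaelis",
    "alpha": 0.05,           # Duncan significance level
    "n_boot": 2000,
    "decomposition": "log",
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _constants_map(cfg: Mapping[str, Any]):
    section = cfg.get("constants") or {}
    out = {}
    for sp in Species:
        shared = {
            k: v for k, v in section.items()
            if k not in (s.value for s in Species) and not isinstance(v, dict)
        }
        shared.update(section.get(sp.value) or {})
        out[sp] = for_species(sp, shared)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def fluorescence_stage(leaf_df: pd.DataFrame) -> pd.DataFrame:
    df = leaf_df.copy()
    df["phi_psii"] = phi_psii(df["Fs"].to_numpy(), df["Fm_prime"].to_numpy())
    df["J"] = electron_transport(
        df["phi_psii"].to_numpy(), df["PPFD"].to_numpy(),
        df["alpha"].to_numpy(), df["beta"].to_numpy(),
    )
    return df


def c3_stage(df: pd.DataFrame, constants_map, rd_fraction: float) -> pd.DataFrame:
    """Variable-J stage for the C3 rows; maize rows pass through."""
    out = df.copy()
    for col in ("AG", "Cc", "gm"):
        if col not in out:
            out[col] = np.nan
    if "feasible" not in out:
        out["feasible"] = True
    mask = ~out["is_c4"].astype(bool)
    for idx in out.index[mask]:
        row = out.loc[idx]
        consts = constants_map[Species(row["species"])]
        res = c3.variable_j_result(
            row["AN"], row["Ci"], row["Rdark"], row["J"], consts, rd_fraction
        )
        out.loc[idx, ["AG", "Cc", "gm"]] = (res.AG, res.Cc, res.gm)
        out.loc[idx, "feasible"] = bool(res.feasible)
    return out


def c4_stage(
    df: pd.DataFrame,
    curves,
    constants_map,
    vp_source: str = "michaelis",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bundle-sheath stage for the maize rows; returns (df, hyperbola table)."""
    out = df.copy()
    for col in ("Cm", "Cs", "Vp", "leak"):
        if col not in out:
            out[col] = np.nan
    fits = {}
    fit_rows = []
    for curve in curves:
        fit = c4.fit_aci_hyperbola(curve)
        fits[(curve.treatment.label, curve.replicate_id)] = fit
        fit_rows.append(
            {
                "species": curve.treatment.species.value,
                "treatment": curve.treatment.label,
                "replicate_id": curve.replicate_id,
                "Amax": fit.Amax,
                "K": fit.K,
                "rmse": fit.rmse,
                "degenerate": fit.degenerate,
            }
        )
    mask = out["is_c4"].astype(bool)
    for idx in out.index[mask]:
        row = out.loc[idx]
        consts = constants_map[Species(row["species"])]
        fit = fits.get((row["treatment"], row["replicate_id"]))
        res = c4.estimate_cs(
            row["AN"], row["Ci"], row["Rdark"], consts,
            vp_source=vp_source, hyperbola=fit,
        )
        out.loc[idx, ["Cm", "Cs", "Vp", "leak"]] = (
            res.Cm, res.Cs, res.Vp, res.leak
        )
        out.loc[idx, "feasible"] = bool(res.feasible)
        out.loc[idx, "AG"] = c3.gross_assimilation(row["AN"], row["Rdark"])
        out.loc[idx, "gm"] = consts.gm_c4
    return out, pd.DataFrame(fit_rows)


def biochem_stage(
    bio_df: pd.DataFrame, constants_map, tsp_per_area: float
) -> pd.DataFrame:
    out = bio_df.copy()
    acts, vcmaxes = [], []
    for _, row in out.iterrows():
        consts = constants_map[Species(row["species"])]
        act = activation_state(row["initial_activity"], row["total_activity"])
        vc = vcmax_biochemical(
            VcmaxInput(
                rubisco_area_density=rubisco_area_density(
                    row["rubisco_amount"], tsp_per_area
                ),
                activation_state=act,
                kcat=consts.kcat,
                molar_mass=consts.rubisco_molar_mass,
                sites=consts.sites_per_holoenzyme,
            )
        )
        acts.append(act)
        vcmaxes.append(vc)
    out["activation_state"] = acts
    out["Vcmax"] = vcmaxes
    out["rca_rubisco_ratio"] = out["rca_total"] / out["rubisco_amount"]
    return out


def merge_derived(leaf_df: pd.DataFrame, bio_df: pd.DataFrame) -> pd.DataFrame:
    keys = ["species", "treatment", "replicate_id"]
    bio_cols = keys + [
        "initial_activity", "total_activity", "rubisco_amount",
        "activation_state", "Vcmax", "rca_total", "rca_large", "rca_small",
        "rca_rubisco_ratio",
    ]
    merged = leaf_df.merge(bio_df[bio_cols], on=keys, how="left")
    merged["gs_co2"] = merged["gs"] / GS_H2O_TO_CO2
    merged["C"] = np.where(merged["is_c4"], merged.get("Cs"), merged["Cc"])
    return merged


def limitations_stage(
    derived: pd.DataFrame,
    constants_map,
    method: str = "log",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Control-referenced decomposition per species x stressed treatment."""
    from .datamodel import treatment_from_label

    rows = []
    usable = derived[
        derived["feasible"].astype(bool) & derived["C"].notna()
        & derived["Vcmax"].notna()
    ]
    for species, sdf in usable.groupby("species", sort=True):
        sp = Species(species)
        consts = constants_map[sp]
        ref = sdf[sdf["treatment"] == "control"]
        if ref.empty:
            raise PhotolimError(f"no control replicates for {species}")
        for label in ("WD", "HT", "HT-WD"):
            stressed = sdf[sdf["treatment"] == label]
            if stressed.empty:
                continue
            cell_tag = zlib.crc32(f"{species}|{label}".encode()) % 2**20
            rng = np.random.default_rng(seed + cell_tag)
            boot = bootstrap_partition(
                ref, stressed, consts,
                treatment=treatment_from_label(sp, label),
                reference=treatment_from_label(sp, "control"),
                c4=sp.is_c4, method=method, n_boot=n_boot, rng=rng,
            )
            res = boot["result"]
            rows.append(
                {
                    "species": species,
                    "treatment": label,
                    "reference": "control",
                    "SL": res.SL, "MCL": res.MCL, "BL": res.BL, "DL": res.DL,
                    "SL_frac": res.SL_frac, "MCL_frac": res.MCL_frac,
                    "BL_frac": res.BL_frac,
                    "SL_se": boot["SL_se"], "MCL_se": boot["MCL_se"],
                    "BL_se": boot["BL_se"], "DL_se": boot["DL_se"],
                    "n_ref": len(ref), "n_stressed": len(stressed),
                }
            )
    return pd.DataFrame(rows)


def stats_stage(
    derived: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Factorial ANOVA, Duncan letters and the trait regressions."""
    derived = derived.copy()
    derived["irrigation"] = np.where(
        derived["treatment"].isin(["WD", "HT-WD"]), "WD", "WW"
    )
    derived["temperature"] = np.where(
        derived["treatment"].isin(["HT", "HT-WD"]), "HT38", "control25"
    )
    responses = [
        c for c in ("AN", "gs", "J", "activation_state", "Vcmax", "AG")
        if c in derived.columns and derived[c].notna().all()
    ]
    anova_rows = []
    for resp in responses:
        table = factorial_anova(
            derived, resp, ["species", "irrigation", "temperature"]
        ).table
        for effect, row in table.iterrows():
            anova_rows.append(
                {"response": resp, "effect": effect, **row.to_dict()}
            )
    anova_df = pd.DataFrame(anova_rows)

    duncan_rows = []
    for resp in responses:
        for species, sdf in derived.groupby("species", sort=True):
            groups = [
                (label, g[resp].to_numpy())
                for label, g in sdf.groupby("treatment", sort=True)
                if g[resp].notna().all() and len(g) >= 2
            ]
            if len(groups) < 2:
                continue
            grouping = duncan_test(groups, alpha=alpha)
            for lab, mean in zip(grouping.labels, grouping.means):
                duncan_rows.append(
                    {
                        "response": resp,
                        "species": species,
                        "treatment": lab,
                        "mean": mean,
                        "letters": grouping.letters[lab],
                    }
                )
    duncan_df = pd.DataFrame(duncan_rows)

    reg_rows = []
    specs = [
        ("AN_vs_activation_WW", "activation_state", "AN",
         derived[derived["irrigation"] == "WW"]),
        ("activation_vs_J", "J", "activation_state", derived),
        ("rca_rubisco_vs_C", "C", "rca_rubisco_ratio", derived),
    ]
    for name, xcol, ycol, frame in specs:
        for species, sdf in frame.groupby("species", sort=True):
            sub = sdf[[xcol, ycol]].dropna()
            if len(sub) < 3 or sub[xcol].nunique() < 2:
                continue
            res = simple_regression(sub[xcol], sub[ycol])
            reg_rows.append(
                {
                    "relationship": name, "species": species,
                    "slope": res.slope, "intercept": res.intercept,
                    "r2": res.r2, "p": res.p, "n": res.n,
                }
            )
    return anova_df, duncan_df, pd.DataFrame(reg_rows)


# ---------------------------------------------------------------------------
# top-level runs
# ---------------------------------------------------------------------------

def simulate_to_dir(out_dir: str | Path, seed: int, config=None) -> Path:
    """Write a synthetic experiment's three input CSVs + ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or default_study_config()
    exp = generate_experiment(config, seed)
    write_leaf_records(exp.leaf_records, out_dir / "leaf_records.csv")
    write_aci_curves(exp.aci_curves, out_dir / "aci_curves.csv")
    write_biochem_records(exp.biochem_records, out_dir / "biochem.csv")
    exp.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None,
    input_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Execute every stage on the CSVs in ``input_dir``; write outputs.

    Returns the run manifest (also written as ``manifest.json``). Raises
    on hard stage failures; soft issues (clipped activation states,
    infeasible variable-J records, negative limitation components) are
    warnings, counted in the manifest.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config) if not isinstance(config, Mapping) else {
        **DEFAULT_CONFIG, **dict(config)
    }
    constants_map = _constants_map(cfg)
    maps = cfg.get("column_maps") or {}

    caught: list[warnings.WarningMessage] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        log.info("[read] loading input tables from %s", input_dir)
        leaves = read_leaf_records(
            input_dir / "leaf_records.csv", maps.get("leaf_records")
        )
        curves_path = input_dir / "aci_curves.csv"
        curves = (
            read_aci_curves(curves_path, maps.get("aci_curves"))
            if curves_path.exists() else []
        )
        bio = read_biochem_records(
            input_dir / "biochem.csv", maps.get("biochem")
        )

        log.info("[fluorescence] PhiPSII and J for %d leaves", len(leaves))
        leaf_df = fluorescence_stage(leaf_records_frame(leaves))

        log.info("[c3] variable-J gm/Cc")
        leaf_df = c3_stage(leaf_df, constants_map, cfg["rd_fraction"])

        log.info("[c4] hyperbola fits and bundle-sheath Cs")
        leaf_df, hyper_df = c4_stage(
            leaf_df, curves, constants_map, cfg["vp_source"]
        )

        log.info("[biochem] activities, activation state, Vcmax")
        bio_df = biochem_stage(
            biochem_records_frame(bio), constants_map, cfg["tsp_per_area"]
        )

        derived = merge_derived(leaf_df, bio_df)

        log.info("[limitations] control-referenced decomposition")
        lim_df = limitations_stage(
            derived, constants_map,
            method=cfg["decomposition"], n_boot=cfg["n_boot"], seed=seed,
        )

        log.info("[stats] ANOVA, Duncan letters, regressions")
        anova_df, duncan_df, reg_df = stats_stage(derived, cfg["alpha"])

    float_fmt = "%.17g"  # exact float round trip; keeps DL == SL + MCL on disk
    derived.to_csv(out_dir / "derived_records.csv", index=False,
                   float_format=float_fmt)
    hyper_df.to_csv(out_dir / "hyperbola_fits.csv", index=False,
                    float_format=float_fmt)
    lim_df.to_csv(out_dir / "limitations.csv", index=False,
                  float_format=float_fmt)
    anova_df.to_csv(out_dir / "anova.csv", index=False, float_format=float_fmt)
    duncan_df.to_csv(out_dir / "duncan_letters.csv", index=False,
                     float_format=float_fmt)
    reg_df.to_csv(out_dir / "regressions.csv", index=False,
                  float_format=float_fmt)

    warn_counts: dict[str, int] = {}
    for w in caught:
        key = str(w.message).split("(")[0].strip()[:60]
        warn_counts[key] = warn_counts.get(key, 0) + 1
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": {k: v for k, v in cfg.items() if k != "column_maps"},
        "constants_provenance": {
            sp.value: dict(constants_map[sp].provenance) for sp in Species
            if sp in constants_map
        },
        "n_leaf_records": len(leaves),
        "n_aci_curves": len(curves),
        "n_biochem_records": len(bio),
        "n_infeasible_records": int((~derived["feasible"].astype(bool)).sum()),
        "warnings": warn_counts,
        "outputs": sorted(
            p.name for p in out_dir.glob("*.csv")
        ) + ["manifest.json"],
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
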