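"""Delimited-text readers/writers for leaf, A-Ci and biochemistry records.

Instrument exports vary in their column names, so every reader accepts a
``column_map`` ({canonical name: file column name}). Files are
comma-separated UTF-8 with '.' decimals by default; round trips are
lossless at full float precision (pandas ``repr`` formatting).
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import (
    ACiCurve,
    BiochemRecord,
    LeafRecord,
    Species,
    Treatment,
    treatment_from_label,
)
from .errors import SchemaError, ValidationError

_TREATMENT_COLS = ("species", "treatment", "replicate_id")

_LEAF_COLS = (
    "AN", "gs", "Ci", "Ca", "PPFD", "Tleaf", "Rdark",
    "Fs", "Fm_prime", "alpha", "beta",
)
_BIOCHEM_COLS = (
    "initial_activity", "total_activity", "rubisco_amount",
    "rca_total", "rca_large", "rca_small",
)
_BIOCHEM_OPTIONAL = ("rca_total", "rca_large", "rca_small", "tsp_conc")


def _read_table(
    path: str | Path,
    mandatory: Sequence[str],
    column_map: Mapping[str, str] | None,
    sep: str = ",",
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        # round_trip: shortest-repr floats must survive write -> read
        df = pd.read_csv(
            path, sep=sep, encoding="utf-8", float_precision="round_trip"
        )
    except Exception as exc:  # malformed file
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def _treatment(row: pd.Series) -> Treatment:
    return treatment_from_label(Species(str(row["species"])), str(row["treatment"]))


def _collect(records: list, errors: list[str], what: str):
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid {what} row(s):\n" + "\n".join(errors)
        )
    return records


def read_leaf_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[LeafRecord]:
    """Read validated leaf records; invalid rows are reported by row number."""
    df = _read_table(path, _TREATMENT_COLS + _LEAF_COLS, column_map, sep)
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            records.append(
                LeafRecord(
                    treatment=_treatment(row),
                    replicate_id=str(row["replicate_id"]),
                    **{c: float(row[c]) for c in _LEAF_COLS},
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"  row {i + 2}: {exc}")  # +2: header + 1-based
    return _collect(records, errors, "leaf record")


def write_leaf_records(records: Iterable[LeafRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "species": r.treatment.species.value,
            "treatment": r.treatment.label,
            "replicate_id": r.replicate_id,
        }
        row.update({c: getattr(r, c) for c in _LEAF_COLS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aci_curves(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[ACiCurve]:
    """Read A-Ci curves from long format (one row per point).

    Points belonging to one curve share (species, treatment, replicate_id);
    they are sorted by Ci within each curve.
    """
    df = _read_table(path, _TREATMENT_COLS + ("Ci", "AN"), column_map, sep)
    curves, errors = [], []
    for key, grp in df.groupby(list(_TREATMENT_COLS), sort=True):
        grp = grp.sort_values("Ci")
        try:
            curves.append(
                ACiCurve(
                    treatment=_treatment(grp.iloc[0]),
                    replicate_id=str(key[2]),
                    points=tuple(zip(grp["Ci"].astype(float), grp["AN"].astype(float))),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"  curve {key}: {exc}")
    return _collect(curves, errors, "A-Ci curve")


def write_aci_curves(curves: Iterable[ACiCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for ci, an in c.points:
            rows.append(
                {
                    "species": c.treatment.species.value,
                    "treatment": c.treatment.label,
                    "replicate_id": c.replicate_id,
                    "Ci": ci,
                    "AN": an,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_biochem_records(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[BiochemRecord]:
    mandatory = _TREATMENT_COLS + tuple(
        c for c in _BIOCHEM_COLS if c not in _BIOCHEM_OPTIONAL
    )
    df = _read_table(path, mandatory, column_map, sep)
    records, errors = [], []
    for i, row in df.iterrows():
        kwargs = {}
        for c in _BIOCHEM_COLS + ("tsp_conc",):
            if c in df.columns and pd.notna(row.get(c)):
                kwargs[c] = float(row[c])
        try:
            records.append(
                BiochemRecord(
                    treatment=_treatment(row),
                    replicate_id=str(row["replicate_id"]),
                    **kwargs,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"  row {i + 2}: {exc}")
    return _collect(records, errors, "biochemistry")


def write_biochem_records(
    records: Iterable[BiochemRecord], path: str | Path
) -> None:
    rows = []
    for r in records:
        row = {
            "species": r.treatment.species.value,
            "treatment": r.treatment.label,
            "replicate_id": r.replicate_id,
        }
        row.update({c: getattr(r, c) for c in _BIOCHEM_COLS})
        if r.tsp_conc is not None:
            row["tsp_conc"] = r.tsp_conc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def leaf_records_frame(records: Iterable[LeafRecord]) -> pd.DataFrame:
    """Leaf records as a tidy DataFrame (one row per leaf)."""
    rows = []
    for r in records:
        row = {
            "species": r.treatment.species.value,
            "treatment": r.treatment.label,
            "replicate_id": r.replicate_id,
            "is_c4": r.treatment.is_c4,
        }
        row.update({c: getattr(r, c) for c in _LEAF_COLS})
        rows.append(row)
    return pd.DataFrame(rows)


def biochem_records_frame(records: Iterable[BiochemRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "species": r.treatment.species.value,
            "treatment": r.treatment.label,
            "replicate_id": r.replicate_id,
        }
        row.update({c: getattr(r, c) for c in _BIOCHEM_COLS})
        rows.append(row)
    return pd.DataFrame(rows)
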