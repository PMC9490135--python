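"""CSV dialects and sidecar files shared by the generator, prep, and CLI.

Formats (all plain text, empty cells = missing):

* ``birds.csv``      — bird_id,age,mass_g,wing_mm,tarsus_mm,culmen_mm,fcort_pg_mm
* ``locations.csv``  — bird_id,x,y,year,horse_use,cow_use,precip_mm,grass_pct
* ``encounters.csv`` — bird_id,week,date,state  (state in alive/dead/censored)
* ``breeding.csv``   — bird_id,ybp,yns,ybs,yf
* ``analysis.csv``   — one row per bird: raw + standardized covariates + fCort
* ``scaling.json``   — sidecar with the standardization constants
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .covariates import (CONTINUOUS_EFFECTS, DesignMatrixBuilder,
                         average_covariates, body_condition, build_design)

__all__ = [
    "write_birds", "read_birds", "write_locations", "read_locations",
    "write_encounters", "read_encounters", "write_breeding", "read_breeding",
    "write_analysis", "read_analysis", "write_scaling", "read_scaling",
    "prepare_analysis",
]

BIRD_COLUMNS = ["bird_id", "age", "mass_g", "wing_mm", "tarsus_mm",
                "culmen_mm", "fcort_pg_mm"]
LOCATION_COLUMNS = ["bird_id", "x", "y", "year", "horse_use", "cow_use",
                    "precip_mm", "grass_pct"]
ENCOUNTER_COLUMNS = ["bird_id", "week", "date", "state"]
BREEDING_COLUMNS = ["bird_id", "ybp", "yns", "ybs", "yf"]

#: locations.csv column -> model covariate name
LOCATION_RENAME = {"horse_use": "horses", "cow_use": "cows",
                   "precip_mm": "precipitation", "grass_pct": "annual_grass"}


def _write(df: pd.DataFrame, path, columns) -> None:
    df.to_csv(path, index=False, columns=[c for c in columns if c in df.columns])


def _read(path, required) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_birds(df, path):
    _write(df, path, BIRD_COLUMNS)


def read_birds(path):
    return _read(path, ["bird_id", "age", "fcort_pg_mm"])


def write_locations(df, path):
    _write(df, path, LOCATION_COLUMNS)


def read_locations(path):
    return _read(path, LOCATION_COLUMNS)


def write_encounters(df, path):
    _write(df, path, ENCOUNTER_COLUMNS)


def read_encounters(path):
    return _read(path, ENCOUNTER_COLUMNS)


def write_breeding(df, path):
    _write(df, path, BREEDING_COLUMNS)


def read_breeding(path):
    return _read(path, BREEDING_COLUMNS)


def write_analysis(df, path):
    df.to_csv(path, index=False)


def read_analysis(path):
    return _read(path, ["bird_id", "fcort_pg_mm"])


def write_scaling(builder: DesignMatrixBuilder, path) -> None:
    """Standardization constants sidecar (JSON)."""
    payload = {name: {"mean": m, "sd": s} for name, (m, s) in builder.scale_.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_scaling(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {name: (v["mean"], v["sd"]) for name, v in payload.items()}


def design_from_analysis(df: pd.DataFrame) -> pd.DataFrame:
    """Reassemble the standardized 9-column design from an analysis table."""
    from .covariates import TERMS
    cols = {}
    for term in TERMS:
        if term == "intercept":
            continue
        name = f"z_{term}" if f"z_{term}" in df.columns else term
        if name not in df.columns:
            raise ValueError(f"analysis table missing design column {term!r}")
        cols[term] = df[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def prepare_analysis(birds: pd.DataFrame, locations: pd.DataFrame):
    """Raw field tables -> analysis table + fitted design builder.

    Averages per-location covariates to the bird level, computes the
    body-condition residual from morphometrics (mean-imputing incomplete
    birds), standardizes, and forms the interaction columns.

    Returns ``(analysis, design, builder)``: the per-bird table with raw
    covariates plus ``z_``-prefixed standardized columns, the bare
    9-column design matrix, and the builder holding scaling constants.
    """
    avg = average_covariates(
        locations, value_columns=["horse_use", "cow_use", "precip_mm", "grass_pct"])
    avg = avg.rename(columns=LOCATION_RENAME)
    # a birds table may already carry covariate columns (e.g. generator
    # output); the location-derived values are authoritative here
    birds = birds.drop(columns=[c for c in LOCATION_RENAME.values()
                                if c in birds.columns])
    merged = birds.merge(avg, on="bird_id", how="left", validate="one_to_one")
    missing = merged[merged[list(LOCATION_RENAME.values())].isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"no locations for bird(s): {missing['bird_id'].tolist()[:5]}")
    merged["body_condition"] = body_condition(merged)
    design, builder = build_design(merged)
    analysis = merged.copy()
    for c in design.columns:
        analysis[f"z_{c}" if c in CONTINUOUS_EFFECTS else c] = design[c]
    return analysis, design, builder
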