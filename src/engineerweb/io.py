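"""Delimited-table readers/writers and the structured run report.

All tables are UTF-8 text with a required header row; comma-delimited by
default, tab-delimited when ``dialect="tab"``.  Numeric fields round-trip
at 12 significant digits.  Decimal separator is always the point,
independent of locale.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (CoefficientTable, CommunityMatrix, IsotopeTable,
                        RunConfig, ValidationError, check_habitat)

log = logging.getLogger("engineerweb")

_FLOAT_FMT = "%.12g"


def _sep(dialect: str) -> str:
    return {"csv": ",", "tab": "\t"}[dialect]


# ---------------------------------------------------------------- community

COMMUNITY_COLUMNS = ["bay", "habitat", "haul", "species",
                     "biomass_kg_km2", "density_n_km2"]


def read_community(path, surfaces=None, dialect: str = "csv") -> CommunityMatrix:
    """Read a haul x species community table.

    Accepts the long layout (one row per haul-species pair, columns
    ``bay,habitat,haul,species,biomass_kg_km2,density_n_km2``) or the wide
    layout (``bay,habitat,haul,layer`` followed by one column per species,
    ``layer`` in {biomass, density}).  The layout is auto-detected from the
    header.  Species absent from a haul become explicit zeros.

    ``surfaces`` is an optional path to a ``bay,habitat,surface_km2`` table.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    if "species" in df.columns:
        matrix = _community_from_long(df)
    elif "layer" in df.columns:
        matrix = _community_from_wide(df)
    else:
        raise ValidationError(
            "community file is neither long (needs 'species' column) "
            "nor wide (needs 'layer' column)")
    if surfaces is not None:
        matrix.surface.update(read_surfaces(surfaces, dialect=dialect))
    return matrix


def _community_from_long(df: pd.DataFrame) -> CommunityMatrix:
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"community file missing columns {missing}")
    for h in df["habitat"].unique():
        check_habitat(h)
    neg = df[df["biomass_kg_km2"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise ValidationError(
            f"negative biomass for haul {row['haul']!r} "
            f"species {row['species']!r}")
    key = ["bay", "habitat", "haul", "species"]
    dup = df[df.duplicated(subset=key, keep=False)]
    if len(dup):
        row = dup.iloc[0]
        raise ValidationError(
            f"duplicate (haul, species) pair: ({row['haul']!r}, "
            f"{row['species']!r})")
    idx = ["bay", "habitat", "haul"]
    biomass = (df.pivot_table(index=idx, columns="species",
                              values="biomass_kg_km2", fill_value=0.0,
                              aggfunc="sum")
               .sort_index().sort_index(axis=1))
    density = (df.pivot_table(index=idx, columns="species",
                              values="density_n_km2", fill_value=0.0,
                              aggfunc="sum")
               .sort_index().sort_index(axis=1))
    biomass.columns.name = None
    density.columns.name = None
    return CommunityMatrix(biomass=biomass.astype(float),
                           density=density.astype(float))


def _community_from_wide(df: pd.DataFrame) -> CommunityMatrix:
    for h in df["habitat"].unique():
        check_habitat(h)
    idx = ["bay", "habitat", "haul"]
    layers = {}
    for layer in ("biomass", "density"):
        sub = df[df["layer"] == layer].drop(columns="layer")
        if sub.empty:
            raise ValidationError(f"wide community file lacks layer {layer!r}")
        if sub.duplicated(subset=idx).any():
            raise ValidationError(f"duplicate haul rows in layer {layer!r}")
        layers[layer] = (sub.set_index(idx).astype(float)
                         .sort_index().sort_index(axis=1))
    return CommunityMatrix(biomass=layers["biomass"],
                           density=layers["density"])


def write_community(matrix: CommunityMatrix, path, dialect: str = "csv") -> None:
    """Write a community matrix in the long layout (zeros included)."""
    b = matrix.biomass.stack()
    d = matrix.density.stack()
    out = pd.DataFrame({"biomass_kg_km2": b, "density_n_km2": d})
    out.index.names = ["bay", "habitat", "haul", "species"]
    out.reset_index().to_csv(path, sep=_sep(dialect), index=False,
                             float_format=_FLOAT_FMT)


def read_surfaces(path, dialect: str = "csv") -> dict:
    df = pd.read_csv(path, sep=_sep(dialect))
    out = {}
    for _, row in df.iterrows():
        check_habitat(row["habitat"])
        s = float(row["surface_km2"])
        if not s > 0:
            raise ValidationError(
                f"surface must be > 0 for ({row['bay']}, {row['habitat']})")
        out[(row["bay"], row["habitat"])] = s
    return out


def write_surfaces(surface: Mapping, path, dialect: str = "csv") -> None:
    rows = [{"bay": b, "habitat": h, "surface_km2": s}
            for (b, h), s in surface.items()]
    pd.DataFrame(rows).to_csv(path, sep=_sep(dialect), index=False,
                              float_format=_FLOAT_FMT)


# ----------------------------------------------------------------- isotopes

def read_isotopes(path, dialect: str = "csv",
                  known_species: Optional[Iterable[str]] = None) -> IsotopeTable:
    """Read the per-replicate isotope table.

    When ``known_species`` is given, replicates of unlisted species are
    excluded with a logged warning instead of failing.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    for h in df["habitat"].unique():
        check_habitat(h)
    if known_species is not None:
        known = set(known_species)
        unknown = sorted(set(df["species"]) - known)
        if unknown:
            log.warning("isotope table: excluding species absent from the "
                        "registry: %s", unknown)
            df = df[df["species"].isin(known)]
    return IsotopeTable(df.reset_index(drop=True))


def write_isotopes(table: IsotopeTable, path, dialect: str = "csv") -> None:
    table.data.to_csv(path, sep=_sep(dialect), index=False,
                      float_format=_FLOAT_FMT)


# ------------------------------------------------------------- coefficients

def read_coefficients(path, dialect: str = "csv") -> CoefficientTable:
    df = pd.read_csv(path, sep=_sep(dialect))
    return CoefficientTable(df.reset_index(drop=True))


def write_coefficients(table: CoefficientTable, path,
                       dialect: str = "csv") -> None:
    table.data.to_csv(path, sep=_sep(dialect), index=False,
                      float_format=_FLOAT_FMT)


# ------------------------------------------------------------------ lengths

def read_lengths(path, dialect: str = "csv") -> pd.DataFrame:
    """Fish length records: bay,habitat,haul,species,length_cm,weight_g."""
    df = pd.read_csv(path, sep=_sep(dialect))
    for h in df["habitat"].unique():
        check_habitat(h)
    if (df["length_cm"] < 0).any():
        raise ValidationError("negative length in length records")
    return df


def write_lengths(df: pd.DataFrame, path, dialect: str = "csv") -> None:
    df.to_csv(path, sep=_sep(dialect), index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------------- report

def _flatten(obj, prefix=""):
    """Flatten nested dict/dataclass/scalar structures to key -> value."""
    out = {}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            out.update(_flatten(v, key))
    elif isinstance(obj, (list, tuple, np.ndarray)):
        for i, v in enumerate(np.asarray(obj).ravel()
                              if isinstance(obj, np.ndarray) else obj):
            out.update(_flatten(v, f"{prefix}[{i}]"))
    else:
        if isinstance(obj, (np.floating, np.integer)):
            obj = obj.item()
        out[prefix] = obj
    return out


def write_report(results: Mapping[str, object], out_dir,
                 config: Optional[RunConfig] = None,
                 dialect: str = "csv") -> list[str]:
    """Write one flat key/value summary table per stage plus a config echo.

    ``results`` maps stage name to any nested structure of dicts,
    dataclasses and scalars; DataFrames are written verbatim as
    ``<stage>.csv`` companions.  Returns the list of files written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for stage, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{stage}.csv")
            obj.to_csv(path, sep=_sep(dialect), index=False,
                       float_format=_FLOAT_FMT)
            written.append(path)
            continue
        flat = _flatten(obj)
        path = os.path.join(out_dir, f"{stage}_summary.csv")
        pd.DataFrame({"key": list(flat), "value": list(flat.values())}) \
            .to_csv(path, sep=_sep(dialect), index=False)
        written.append(path)
    if config is not None:
        path = os.path.join(out_dir, "run_config.json")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2)
        written.append(path)
    return written
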