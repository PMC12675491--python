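"""Delimited-table readers and writers.

Trait and observation tables are comma-separated UTF-8 text with two
header lines: column names, then the unit of each column (``-`` for
labels and dimensionless quantities).  All values are converted to SI at
read time; writers emit SI with an explicit units row, so a
write-then-read round trip is lossless.

Trait table columns (presence depends on morphology):

    specimen_id, species, morphology, volume, wet_weight,
    projection_area, branch_width, axis_a, axis_b, axis_c

Observation table columns:

    specimen_id, replicate, omega, and either (temperature, salinity)
    or (rho_sw, nu); optional g and floating.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidityError
from .medium import STANDARD_GRAVITY, seawater_density, seawater_viscosity
from .traits import (
    corey_shape_factor,
    mass_density,
    nominal_diameter,
    shape_factor_branched,
    shape_factor_flattened,
)

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_observation_table",
    "write_observation_table",
    "write_json_report",
]

_UNIT_FACTORS = {
    "m^3": 1.0, "m3": 1.0, "cm^3": 1e-6, "cm3": 1e-6, "mm^3": 1e-9, "ml": 1e-6, "l": 1e-3,
    "kg": 1.0, "g": 1e-3, "mg": 1e-6,
    "m^2": 1.0, "m2": 1.0, "cm^2": 1e-4, "cm2": 1e-4, "mm^2": 1e-6,
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6,
    "m/s": 1.0, "m s^-1": 1.0, "cm/s": 1e-2, "mm/s": 1e-3,
    "kg/m^3": 1.0, "kg m^-3": 1.0, "g/cm^3": 1e3,
    "m^2/s": 1.0, "m2/s": 1.0, "m^2 s^-1": 1.0,
    "m/s^2": 1.0, "m s^-2": 1.0,
    "-": 1.0, "": 1.0, "1": 1.0, "degc": 1.0, "psu": 1.0, "count": 1.0,
}

_LABEL_COLUMNS = {"specimen_id", "species", "morphology", "route", "floating", "replicate"}


def _unit_factor(column: str, unit: str) -> float:
    key = str(unit).strip().lower()
    if key in ("nan", "none"):
        key = "-"
    if key not in _UNIT_FACTORS:
        raise SchemaError(f"unknown unit {unit!r} for column {column!r}")
    return _UNIT_FACTORS[key]


def _read_with_units(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"table not found: {path}")
    head = pd.read_csv(path, nrows=0)
    units = pd.read_csv(path, skiprows=1, nrows=1, header=None)
    if units.empty:
        raise SchemaError(f"{path}: missing units row (second line)")
    df = pd.read_csv(path, skiprows=2, header=None, names=list(head.columns))
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    unit_row = dict(zip(head.columns, units.iloc[0].astype(str)))
    for col in df.columns:
        if col in _LABEL_COLUMNS:
            continue
        factor = _unit_factor(col, unit_row.get(col, "-"))
        df[col] = pd.to_numeric(df[col], errors="coerce") * factor
    return df


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")


def read_trait_table(path) -> pd.DataFrame:
    """Read a trait table, convert to SI, and derive rho, d_n, s_f.

    Rows that fail validation are collected and reported together with
    their line numbers in a single :class:`SchemaError`.
    """
    df = _read_with_units(path)
    _require_columns(df, ("specimen_id", "morphology", "volume", "wet_weight"), path)
    derived = {"rho": [], "d_n": [], "s_f": [], "route": []}
    errors = []
    for i, rec in df.iterrows():
        line = i + 3  # 1-based, after two header lines
        try:
            v, w = float(rec["volume"]), float(rec["wet_weight"])
            if not (math.isfinite(v) and math.isfinite(w)):
                raise ValidityError("non-numeric volume or wet_weight")
            rho = mass_density(w, v)
            d_n = nominal_diameter(v)
            morph = rec["morphology"]
            if morph == "flattened":
                _, s_f = shape_factor_flattened(float(rec["projection_area"]), v)
            elif morph == "cylindrical_or_branched":
                _, s_f = shape_factor_branched(float(rec["branch_width"]), v)
            elif morph == "direct_axes":
                s_f = corey_shape_factor(
                    float(rec["axis_a"]), float(rec["axis_b"]), float(rec["axis_c"])
                )
            else:
                raise ValidityError(f"unknown morphology {morph!r}")
            derived["rho"].append(rho)
            derived["d_n"].append(d_n)
            derived["s_f"].append(s_f)
            derived["route"].append(morph)
        except (ValidityError, KeyError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} bad rows:\n" + "\n".join(errors))
    for col, values in derived.items():
        df[col] = values
    return df


_SI_UNITS = {
    "volume": "m^3", "wet_weight": "kg", "projection_area": "m^2",
    "branch_width": "m", "axis_a": "m", "axis_b": "m", "axis_c": "m",
    "rho": "kg/m^3", "rho_sw": "kg/m^3", "d_n": "m", "s_f": "-",
    "omega": "m/s", "nu": "m^2/s", "g": "m/s^2",
    "temperature": "degC", "salinity": "psu",
}


def _write_with_units(df: pd.DataFrame, path) -> None:
    units = [("-" if c in _LABEL_COLUMNS else _SI_UNITS.get(c, "-")) for c in df.columns]
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(",".join(units) + "\n")
        df.to_csv(fh, header=False, index=False, float_format="%.12g")


def write_trait_table(df: pd.DataFrame, path) -> None:
    """Write a trait table (SI units, units header row, 12 s.f.)."""
    _write_with_units(df, path)


def write_observation_table(df: pd.DataFrame, path) -> None:
    """Write an observation table (SI units, units header row, 12 s.f.)."""
    _write_with_units(df, path)


def read_observation_table(path) -> pd.DataFrame:
    """Read settling observations; replicates stay as rows, media per row.

    The medium may be given per row either as (temperature, salinity) —
    converted through the seawater correlations — or directly as
    (rho_sw, nu).  Daily drift of the measurement medium is therefore
    preserved per replicate.  Returns SI columns
    ``specimen_id, replicate, omega, rho_sw, nu, g, floating``.
    """
    df = _read_with_units(path)
    _require_columns(df, ("specimen_id", "omega"), path)
    if "rho_sw" in df.columns and "nu" in df.columns:
        pass
    elif "temperature" in df.columns and "salinity" in df.columns:
        t = df["temperature"].to_numpy(dtype=float)
        s = df["salinity"].to_numpy(dtype=float)
        rho = seawater_density(t, s)
        df["rho_sw"] = rho
        df["nu"] = seawater_viscosity(t, s) / rho
    else:
        raise SchemaError(
            f"{path}: need either (rho_sw, nu) or (temperature, salinity) columns"
        )
    if "g" not in df.columns:
        df["g"] = STANDARD_GRAVITY
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby("specimen_id").cumcount() + 1
    if "floating" not in df.columns:
        df["floating"] = False
    else:
        df["floating"] = df["floating"].astype(str).str.lower().isin(("true", "1", "yes"))
    df["floating"] = df["floating"] | ~np.isfinite(df["omega"].to_numpy(dtype=float))
    return df


def write_json_report(report: dict, path) -> None:
    """Serialise a report dict to pretty-printed JSON."""
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
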