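"""File formats, schemas and run manifests.

Occurrence tables are Darwin Core-like CSV (``species``,
``decimalLatitude``, ``decimalLongitude``; optional ``depth``,
``month``).  Environment grids are NetCDF (classic format, CF-style
variable names ``temperature``/``po2``/``cell_volume``).  Trait and
diagnostic tables are UTF-8 CSV with '.' decimals.  Every output
directory carries a JSON run manifest recording the stage, the exact
configuration and its hash, seeds and row counts, so an identical
manifest reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import SchemaError
from .fitting import FitResult
from .grid import EnvironmentGrid, cell_volumes
from .synth import o2conc_to_po2

__all__ = [
    "read_occurrences", "write_occurrences",
    "read_environment", "write_environment",
    "trait_table_from_fits", "read_trait_table", "write_trait_table",
    "write_manifest", "config_hash",
]

SCHEMA_VERSION = "1"
OCCURRENCE_REQUIRED = ("species", "decimalLatitude", "decimalLongitude")


def read_occurrences(path) -> tuple[pd.DataFrame, dict]:
    """Read and validate an occurrence CSV.

    Rows with missing or out-of-range latitude are dropped and counted;
    longitudes are normalized to [-180, 180).  Returns
    ``(records, counts)``.
    """
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"occurrence file missing columns {missing}; found "
            f"{list(df.columns)}"
        )
    n_read = len(df)
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    ok = lat.between(-90, 90) & lon.notna() & df["species"].notna()
    out = df.loc[ok].copy()
    out["decimalLatitude"] = lat[ok]
    out["decimalLongitude"] = np.mod(lon[ok] + 180.0, 360.0) - 180.0
    counts = {"records_read": int(n_read), "dropped": int(n_read - len(out)),
              "kept": int(len(out))}
    return out.reset_index(drop=True), counts


def write_occurrences(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Environment grids (NetCDF classic via the scipy engine)
# ---------------------------------------------------------------------------

def write_environment(env: EnvironmentGrid, path):
    """Write an environment grid as NetCDF-3 classic."""
    ds = env.to_xarray()
    ds.attrs["schema_version"] = SCHEMA_VERSION
    ds.to_netcdf(path, engine="scipy")


def read_environment(path, o2_is_concentration=False, salinity=35.0
                     ) -> EnvironmentGrid:
    """Read an environment grid from NetCDF.

    Temperature declared in K is converted to degC (conversion is by
    declared units only, never silently).  If ``o2_is_concentration``,
    an ``o2`` variable in umol/kg is converted to pO2 (atm) via the
    solubility adapter.  A grid without ``cell_volume`` must carry
    1D ``lat``/``lon``/``depth_edge`` coordinates from which volumes
    are computed with spherical geometry.
    """
    ds = xr.open_dataset(path, engine="scipy")
    try:
        return environment_from_dataset(ds, o2_is_concentration, salinity)
    finally:
        ds.close()


def environment_from_dataset(ds: xr.Dataset, o2_is_concentration=False,
                             salinity=35.0) -> EnvironmentGrid:
    if "temperature" not in ds:
        raise SchemaError(
            f"missing variable 'temperature'; found {sorted(ds.data_vars)}"
        )
    temp = ds["temperature"]
    units = str(temp.attrs.get("units", "degC"))
    tvals = temp.values.astype(float)
    if units in ("K", "kelvin", "Kelvin"):
        tvals = tvals - 273.15
    elif units not in ("degC", "celsius", "C", "degrees_Celsius"):
        raise SchemaError(f"unsupported temperature units {units!r}")

    if o2_is_concentration:
        if "o2" not in ds:
            raise SchemaError(
                f"missing variable 'o2'; found {sorted(ds.data_vars)}"
            )
        po2 = o2conc_to_po2(ds["o2"].values.astype(float), tvals, salinity)
    else:
        if "po2" not in ds:
            raise SchemaError(
                f"missing variable 'po2'; found {sorted(ds.data_vars)}"
            )
        po2 = ds["po2"].values.astype(float)
        p_units = str(ds["po2"].attrs.get("units", "atm"))
        if p_units != "atm":
            raise SchemaError(f"unsupported po2 units {p_units!r}")

    lat = ds["lat"].values.astype(float)
    lon = ds["lon"].values.astype(float)
    depth = ds["depth"].values.astype(float)
    if "depth_edge" in ds:
        depth_edges = ds["depth_edge"].values.astype(float)
    else:
        mid = 0.5 * (depth[:-1] + depth[1:])
        depth_edges = np.concatenate([[0.0], mid, [2 * depth[-1] - mid[-1]]])

    if "ocean_mask" in ds:
        mask = ds["ocean_mask"].values.astype(bool)
    else:
        mask = np.ones((lat.size, lon.size), dtype=bool)

    if "cell_volume" in ds:
        vol = ds["cell_volume"].values.astype(float)
    else:
        step_lat = np.diff(lat).mean()
        step_lon = np.diff(lon).mean()
        lat_edges = np.concatenate([lat - step_lat / 2, [lat[-1] + step_lat / 2]])
        lon_edges = np.concatenate([lon - step_lon / 2, [lon[-1] + step_lon / 2]])
        vol = cell_volumes(lat_edges, lon_edges, depth_edges)
        vol = np.where(mask[None, :, :], vol, 0.0)

    months = ds["month"].values.astype(int) if "month" in ds.coords else None
    return EnvironmentGrid(lat=lat, lon=lon, depth=depth,
                           depth_edges=depth_edges, T=tvals, pO2=po2,
                           cell_volume=vol, ocean_mask=mask, months=months)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = ["species_id", "A_eco", "E_eco_ref", "dEdT", "T_ref", "F1",
                 "TP", "FP", "FN", "TN", "T_C", "T_W", "Phi_max", "n_cells",
                 "flag"]


def trait_table_from_fits(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        t = f.traits
        rows.append({
            "species_id": f.species_id, "A_eco": t.A_eco,
            "E_eco_ref": t.E_eco_ref, "dEdT": t.dEdT, "T_ref": t.T_ref,
            "F1": f.f1, "TP": f.tp, "FP": f.fp, "FN": f.fn, "TN": f.tn,
            "T_C": f.t_cold, "T_W": f.t_warm, "Phi_max": f.phi_max,
            "n_cells": f.n_presence_cells, "flag": f.flag,
        })
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)


def write_trait_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("species_id", "A_eco", "E_eco_ref") if c not in df]
    if missing:
        raise SchemaError(f"trait table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, stage: str, config: dict, counts: dict,
                   seeds: dict | None = None):
    """Write a deterministic machine-readable run manifest (JSON)."""
    import aerotraits

    manifest = {
        "stage": stage,
        "schema_version": SCHEMA_VERSION,
        "aerotraits_version": aerotraits.__version__,
        "config": config,
        "config_sha256": config_hash(config),
        "seeds": seeds or {},
        "counts": counts,
    }
    Path(path).write_text(json.dumps(manifest, sort_keys=True, indent=1,
                                     default=str) + "\n")
    return manifest
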