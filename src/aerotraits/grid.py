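"""Gridded ocean environment container (temperature, pO2, cell volume).

The grid is cell-centered: latitude ascending, longitude in
[-180, 180), depth positive downward in meters.  Fields are stored as
plain numpy arrays with dims ``(depth, lat, lon)`` for annual grids and
``(month, depth, lat, lon)`` when a monthly climatology is present.
``cell_volume`` is always ``(depth, lat, lon)`` in m^3 and is zero on
land.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .errors import InvalidInputError

__all__ = ["EnvironmentGrid", "cell_volumes"]


def cell_volumes(lat_edges, lon_edges, depth_edges, radius_m=None):
    """Grid-cell volumes (m^3) from spherical-shell geometry.

    Area of a cell is ``R^2 * dlon_rad * (sin(lat2) - sin(lat1))``;
    volume multiplies by the layer thickness (curvature of the thin
    upper-ocean shells is neglected).  Returns array with shape
    ``(n_depth, n_lat, n_lon)``.
    """
    from .constants import EARTH_RADIUS_M

    r = EARTH_RADIUS_M if radius_m is None else radius_m
    lat_edges = np.asarray(lat_edges, dtype=float)
    lon_edges = np.asarray(lon_edges, dtype=float)
    depth_edges = np.asarray(depth_edges, dtype=float)
    sin_lat = np.sin(np.deg2rad(lat_edges))
    band = sin_lat[1:] - sin_lat[:-1]  # (nlat,)
    dlon = np.deg2rad(np.diff(lon_edges))  # (nlon,)
    area = r * r * band[:, None] * dlon[None, :]  # (nlat, nlon)
    dz = np.diff(depth_edges)  # (nz,)
    return dz[:, None, None] * area[None, :, :]


@dataclass
class EnvironmentGrid:
    """Gridded T (degC), pO2 (atm) and cell volume (m^3) climatology."""

    lat: np.ndarray
    lon: np.ndarray
    depth: np.ndarray
    depth_edges: np.ndarray
    T: np.ndarray
    pO2: np.ndarray
    cell_volume: np.ndarray
    ocean_mask: np.ndarray
    months: np.ndarray | None = None

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.pO2 = np.asarray(self.pO2, dtype=float)
        self.cell_volume = np.asarray(self.cell_volume, dtype=float)
        self.ocean_mask = np.asarray(self.ocean_mask, dtype=bool)
        if self.months is not None:
            self.months = np.asarray(self.months, dtype=int)
        self.validate()

    def validate(self):
        nz, ny, nx = self.depth.size, self.lat.size, self.lon.size
        base = (nz, ny, nx)
        expect = base if self.months is None else (self.months.size,) + base
        for name in ("T", "pO2"):
            arr = getattr(self, name)
            if arr.shape != expect:
                raise InvalidInputError(
                    f"{name} shape {arr.shape} != expected {expect}"
                )
        if self.cell_volume.shape != base:
            raise InvalidInputError(
                f"cell_volume shape {self.cell_volume.shape} != {base}"
            )
        if self.ocean_mask.shape != (ny, nx):
            raise InvalidInputError(
                f"ocean_mask shape {self.ocean_mask.shape} != {(ny, nx)}"
            )
        if self.depth_edges.size != nz + 1:
            raise InvalidInputError("depth_edges must have len(depth)+1 entries")
        if np.any(np.diff(self.lat) <= 0):
            raise InvalidInputError("lat must be strictly ascending")
        if np.any(np.diff(self.depth) <= 0):
            raise InvalidInputError("depth must be strictly ascending")
        if np.any(self.cell_volume < 0):
            raise InvalidInputError("cell_volume must be >= 0")
        if np.any(self.cell_volume[:, ~self.ocean_mask] != 0):
            raise InvalidInputError("cell_volume must be zero on land")
        if np.any(self.pO2 < 0):
            raise InvalidInputError("pO2 must be >= 0")
        if np.nanmin(self.T) < -2.5:
            raise InvalidInputError("T below -2.5 C is outside the ocean range")

    # -- convenience -------------------------------------------------

    @property
    def lat_edges(self):
        step = np.diff(self.lat)
        edges = np.concatenate(
            [[self.lat[0] - step[0] / 2], self.lat[:-1] + step / 2,
             [self.lat[-1] + step[-1] / 2]]
        )
        return edges

    @property
    def lon_edges(self):
        step = np.diff(self.lon)
        edges = np.concatenate(
            [[self.lon[0] - step[0] / 2], self.lon[:-1] + step / 2,
             [self.lon[-1] + step[-1] / 2]]
        )
        return edges

    def annual(self):
        """(T, pO2) annual-mean fields with dims (depth, lat, lon)."""
        if self.months is None:
            return self.T, self.pO2
        return self.T.mean(axis=0), self.pO2.mean(axis=0)

    def total_volume(self, depth_band=None):
        """Total ocean volume (m^3), optionally within a depth band."""
        vol = self.cell_volume
        if depth_band is not None:
            top, bottom = depth_band
            sel = (self.depth >= top) & (self.depth < bottom)
            vol = vol[sel]
        return float(vol.sum())

    # -- xarray bridge (NetCDF IO lives in aerotraits.io) ------------

    def to_xarray(self) -> xr.Dataset:
        dims = ("depth", "lat", "lon")
        if self.months is not None:
            dims = ("month",) + dims
        coords = {"lat": self.lat, "lon": self.lon, "depth": self.depth,
                  "depth_edge": self.depth_edges}
        if self.months is not None:
            coords["month"] = self.months
        ds = xr.Dataset(
            {
                "temperature": (dims, self.T, {"units": "degC"}),
                "po2": (dims, self.pO2, {"units": "atm"}),
                "cell_volume": (("depth", "lat", "lon"), self.cell_volume,
                                {"units": "m3"}),
                "ocean_mask": (("lat", "lon"),
                               self.ocean_mask.astype(np.int8)),
            },
            coords=coords,
        )
        ds.attrs["schema_version"] = "1"
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "EnvironmentGrid":
        months = ds["month"].values if "month" in ds.coords else None
        return cls(
            lat=ds["lat"].values,
            lon=ds["lon"].values,
            depth=ds["depth"].values,
            depth_edges=ds["depth_edge"].values,
            T=ds["temperature"].values,
            pO2=ds["po2"].values,
            cell_volume=ds["cell_volume"].values,
            ocean_mask=ds["ocean_mask"].values.astype(bool),
            months=months,
        )
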