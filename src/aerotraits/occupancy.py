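"""Project occurrence records onto the T-pO2 state-space of a grid.

Occurrence rows are snapped to their containing grid cell (half-open
cell intervals, nearest depth level).  The presence universe is the
unique occupied cells; the background universe is every other ocean
cell within the species' occupied depth range extended by a
configurable number of levels (optionally restricted to a latitude
envelope).

By default both universes are then projected onto binned T-pO2 state
space (1 degC temperature bins, 5% multiplicative pO2 bins): presence
samples are the occupied bins, background samples the bins realized by
background cells but never occupied.  This scores the lower pO2
threshold above which occurrences are common and below which they are
rare, rather than raw cell-by-cell overlap — with a few hundred
occurrence records and habitats of 1e4-1e5 grid cells, cell-level F1 is
dominated by unoccupied-but-habitable cells and carries no signal about
the threshold.  Set ``binned=False`` for the raw unique-cell samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SpeciesSkippedError
from .grid import EnvironmentGrid

__all__ = ["OccupancyOptions", "OccupancyDataset", "build_occupancy",
           "empirical_lower_threshold"]

_PO2_FLOOR = 1e-4  # atm; zero-pO2 cells fold into the bottom log bin


@dataclass(frozen=True)
class OccupancyOptions:
    min_cells: int = 10            # minimum unique presence cells
    depth_pad_levels: int = 1      # background depth range extension
    lat_envelope_deg: float | None = 5.0  # latitude band pad (None = global)
    volume_weight: bool = False    # weight samples by cell volume
    missing_depth: str = "surface"  # "surface" | "drop"
    binned: bool = True            # project onto binned T-pO2 state space
    t_bin_c: float = 1.0           # temperature bin width, degC
    po2_bin_frac: float = 0.10     # multiplicative pO2 bin width
    clamp_to_envelope: bool = True  # score only at/below the occupied
    #   upper pO2 envelope per T bin (the fit targets the LOWER threshold;
    #   water richer in O2 than the species ever occupies is uninformative
    #   about that threshold and is excluded from the background universe)
    envelope_pad_bins: int = 1     # background pO2 bins kept above it


@dataclass
class OccupancyDataset:
    """T-pO2 samples with presence/background labels for one species."""

    species_id: str
    T: np.ndarray          # degC, per sample
    pO2: np.ndarray        # atm, per sample
    presence: np.ndarray   # bool, per sample
    weight: np.ndarray     # summed cell volume (m^3) or 1.0, per sample
    n_presence_cells: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.T)
        if not (len(self.pO2) == len(self.presence) == len(self.weight) == n):
            raise InvalidInputError("sample arrays must share length")
        if self.n_presence_cells < 1:
            raise InvalidInputError("need at least one presence cell")

    @property
    def n_background(self) -> int:
        return int((~self.presence).sum())


def _snap_indices(env: EnvironmentGrid, lats, lons, depths):
    """Cell indices (iz, iy, ix) per record; invalid rows flagged False."""
    iy = np.searchsorted(env.lat_edges, lats, side="right") - 1
    ix = np.searchsorted(env.lon_edges, lons, side="right") - 1
    ok = (iy >= 0) & (iy < env.lat.size) & (ix >= 0) & (ix < env.lon.size)
    # nearest depth level: snap by midpoints between level centers
    mid = 0.5 * (env.depth[:-1] + env.depth[1:])
    iz = np.searchsorted(mid, depths, side="right")
    iz = np.clip(iz, 0, env.depth.size - 1)
    return iz, np.where(ok, iy, 0), np.where(ok, ix, 0), ok


def _state_bins(T, pO2, t_bin, po2_frac):
    it = np.floor(T / t_bin).astype(np.int64)
    p = np.maximum(pO2, _PO2_FLOOR)
    ip = np.floor(np.log(p) / np.log1p(po2_frac)).astype(np.int64)
    return it, ip


def _bin_centers(it, ip, t_bin, po2_frac):
    t = (it + 0.5) * t_bin
    p = np.exp((ip + 0.5) * np.log1p(po2_frac))
    return t, p


def _aggregate_bins(T, pO2, w, t_bin, po2_frac):
    """Unique state-space bins with summed weights; returns (it, ip, w)."""
    it, ip = _state_bins(T, pO2, t_bin, po2_frac)
    keys = np.stack([it, ip], axis=1)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    wsum = np.bincount(inv, weights=w, minlength=len(uniq))
    return uniq[:, 0], uniq[:, 1], wsum


def build_occupancy(occurrences: pd.DataFrame, env: EnvironmentGrid,
                    opts: OccupancyOptions | None = None) -> OccupancyDataset:
    """Build the presence/background sample set for one species.

    ``occurrences`` must contain a single species; rows falling on land
    or outside the grid are dropped and counted.  Records with a month
    on a monthly grid use that month's fields; all other values come
    from the annual mean.  Raises :class:`SpeciesSkippedError` when
    fewer than ``opts.min_cells`` unique presence cells remain.
    """
    opts = opts or OccupancyOptions()
    if occurrences.empty:
        raise InvalidInputError("occurrences is empty")
    species = occurrences["species"].unique()
    if len(species) != 1:
        raise InvalidInputError(f"expected one species, got {len(species)}")
    sid = str(species[0])

    lats = occurrences["decimalLatitude"].to_numpy(dtype=float)
    lons = occurrences["decimalLongitude"].to_numpy(dtype=float)
    if "depth" in occurrences.columns:
        depths = pd.to_numeric(occurrences["depth"],
                               errors="coerce").to_numpy(dtype=float)
    else:
        depths = np.full(len(occurrences), np.nan)
    missing_depth = ~np.isfinite(depths)
    if opts.missing_depth == "surface":
        depths = np.where(missing_depth, env.depth[0], depths)
        n_dropped_depth = 0
        keep_depth = np.ones(len(depths), bool)
    elif opts.missing_depth == "drop":
        keep_depth = ~missing_depth
        n_dropped_depth = int(missing_depth.sum())
    else:
        raise InvalidInputError(
            f"unknown missing_depth mode {opts.missing_depth!r}")

    iz, iy, ix, in_grid = _snap_indices(env, lats, lons, depths)
    valid = in_grid & keep_depth
    n_out = int((~in_grid).sum())
    on_land = np.zeros(len(lats), bool)
    on_land[valid] = ~env.ocean_mask[iy[valid], ix[valid]]
    valid &= ~on_land

    months = None
    if "month" in occurrences.columns and env.months is not None:
        months = pd.to_numeric(occurrences["month"],
                               errors="coerce").to_numpy(float)

    T_ann, pO2_ann = env.annual()

    # Unique presence cells, keyed (iz, iy, ix, month-or-0).
    mkey = np.zeros(len(lats), dtype=int)
    if months is not None:
        has_m = np.isfinite(months) & (months >= 1) & (months <= 12)
        mkey = np.where(has_m, months, 0).astype(int)
    keys = np.stack([iz[valid], iy[valid], ix[valid], mkey[valid]], axis=1)
    if keys.size == 0:
        raise SpeciesSkippedError(sid, "no_valid_records")
    cells = np.unique(keys, axis=0)
    n_cells = len(cells)
    if n_cells < opts.min_cells:
        raise SpeciesSkippedError(
            sid, "min_cells", f"{n_cells} unique cells < {opts.min_cells}"
        )

    cz, cy, cx, cm = cells.T
    if env.months is None:
        pres_T = T_ann[cz, cy, cx]
        pres_p = pO2_ann[cz, cy, cx]
    else:
        im = np.clip(np.searchsorted(env.months, cm), 0, len(env.months) - 1)
        monthly = cm > 0
        pres_T = np.where(monthly, env.T[im, cz, cy, cx], T_ann[cz, cy, cx])
        pres_p = np.where(monthly, env.pO2[im, cz, cy, cx],
                          pO2_ann[cz, cy, cx])
    pres_w = (env.cell_volume[cz, cy, cx] if opts.volume_weight
              else np.ones(n_cells))

    # Background domain: ocean cells within the occupied depth range
    # extended by depth_pad_levels, minus presence cells (any month).
    z_lo = max(int(cz.min()) - opts.depth_pad_levels, 0)
    z_hi = min(int(cz.max()) + opts.depth_pad_levels, env.depth.size - 1)
    bg = env.cell_volume > 0
    zmask = np.zeros(env.depth.size, bool)
    zmask[z_lo:z_hi + 1] = True
    bg &= zmask[:, None, None]
    if opts.lat_envelope_deg is not None:
        lat_lo = env.lat[cy].min() - opts.lat_envelope_deg
        lat_hi = env.lat[cy].max() + opts.lat_envelope_deg
        bg &= ((env.lat >= lat_lo) & (env.lat <= lat_hi))[None, :, None]
    occupied = np.zeros(env.cell_volume.shape, bool)
    occupied[cz, cy, cx] = True
    bg &= ~occupied
    bz, by, bx = np.nonzero(bg)
    bg_T = T_ann[bz, by, bx]
    bg_p = pO2_ann[bz, by, bx]
    bg_w = (env.cell_volume[bz, by, bx] if opts.volume_weight
            else np.ones(len(bz)))

    provenance = {
        "records_read": int(len(occurrences)),
        "dropped_out_of_grid": n_out,
        "dropped_on_land": int(on_land.sum()),
        "dropped_missing_depth": n_dropped_depth,
        "matched": int(valid.sum()),
        "unique_cells": n_cells,
        "background_cells": int(len(bz)),
    }

    if opts.binned:
        p_it, p_ip, p_w = _aggregate_bins(pres_T, pres_p, pres_w,
                                          opts.t_bin_c, opts.po2_bin_frac)
        b_it, b_ip, b_w = _aggregate_bins(bg_T, bg_p, bg_w,
                                          opts.t_bin_c, opts.po2_bin_frac)
        # drop background bins that are occupied (disjoint by bin identity)
        pres_keys = set(zip(p_it.tolist(), p_ip.tolist()))
        keep = np.array([(t, p) not in pres_keys
                         for t, p in zip(b_it.tolist(), b_ip.tolist())],
                        dtype=bool)
        b_it, b_ip, b_w = b_it[keep], b_ip[keep], b_w[keep]
        if opts.clamp_to_envelope:
            # keep only background bins in occupied T columns, at or below
            # the occupied upper pO2 envelope (95th percentile per column,
            # robust to stray records, plus a small pad)
            cols = {}
            for t, p in zip(p_it.tolist(), p_ip.tolist()):
                cols.setdefault(t, []).append(p)
            env_top = {t: int(np.ceil(np.percentile(ps, 95)))
                       for t, ps in cols.items()}
            keep = np.array(
                [t in env_top and p <= env_top[t] + opts.envelope_pad_bins
                 for t, p in zip(b_it.tolist(), b_ip.tolist())], dtype=bool)
            b_it, b_ip, b_w = b_it[keep], b_ip[keep], b_w[keep]
        pT, pP = _bin_centers(p_it, p_ip, opts.t_bin_c, opts.po2_bin_frac)
        bT, bP = _bin_centers(b_it, b_ip, opts.t_bin_c, opts.po2_bin_frac)
        if not opts.volume_weight:
            # one vote per realized state-space bin: presence and
            # background universes are counted on the same footing
            p_w = np.ones(len(pT))
            b_w = np.ones(len(bT))
        T_all = np.concatenate([pT, bT])
        p_all = np.concatenate([pP, bP])
        w_all = np.concatenate([p_w, b_w])
        pres_flag = np.concatenate([np.ones(len(pT), bool),
                                    np.zeros(len(bT), bool)])
        provenance["presence_bins"] = int(len(pT))
        provenance["background_bins"] = int(len(bT))
    else:
        T_all = np.concatenate([pres_T, bg_T])
        p_all = np.concatenate([pres_p, bg_p])
        w_all = np.concatenate([pres_w, bg_w])
        pres_flag = np.concatenate([np.ones(n_cells, bool),
                                    np.zeros(len(bz), bool)])

    return OccupancyDataset(
        species_id=sid,
        T=T_all,
        pO2=p_all,
        presence=pres_flag,
        weight=w_all.astype(float),
        n_presence_cells=n_cells,
        provenance=provenance,
    )


def empirical_lower_threshold(dataset: OccupancyDataset, t_bins,
                              quantile=0.05) -> pd.DataFrame:
    """Low quantile of presence pO2 per temperature bin.

    A nonparametric estimate of the occupied lower pO2 envelope as a
    function of temperature, useful for initialization and plots; bins
    with no presence samples carry NaN (missing), never zero.
    """
    t_bins = np.asarray(t_bins, dtype=float)
    if t_bins.size < 2 or np.any(np.diff(t_bins) <= 0):
        raise InvalidInputError("t_bins must be ascending with >= 2 edges")
    T = dataset.T[dataset.presence]
    p = dataset.pO2[dataset.presence]
    idx = np.digitize(T, t_bins) - 1
    lows = np.full(t_bins.size - 1, np.nan)
    for b in range(t_bins.size - 1):
        sel = idx == b
        if sel.any():
            lows[b] = np.quantile(p[sel], quantile)
    return pd.DataFrame({
        "t_left": t_bins[:-1],
        "t_right": t_bins[1:],
        "po2_low": lows,
    })
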