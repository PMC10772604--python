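"""Downstream trait diagnostics.

Habitat volumes over trait space, range-edge temperature sensitivities,
Phi_max/Phi_crit headroom, the temperature sensitivity of the
sustained:resting metabolic-rate ratio (E_phicrit), latitudinal trait
summaries and two-sample Kolmogorov-Smirnov comparisons.

Percentile convention throughout: linear interpolation between closest
ranks (numpy default), used consistently for T_C, T_W and Phi_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CELSIUS_OFFSET, K_B, T_REF_DEFAULT
from .errors import InvalidInputError
from .fitting import FitResult
from .grid import EnvironmentGrid
from .model import TraitSet, metabolic_index

__all__ = [
    "DEFAULT_PHI_MAX",
    "habitat_volume",
    "habitat_volume_grid",
    "HabitatVolumeGrid",
    "EdgeSensitivities",
    "edge_sensitivities",
    "phi_max_ratio",
    "e_phicrit",
    "e_phicrit_from_fas",
    "latitudinal_summary",
    "ks_two_sample",
]

#: Default upper Phi bound for habitat volumes: the median species'
#: maximum occupied Phi relative to Phi_crit is about 1.4.
DEFAULT_PHI_MAX = 1.4


def _band_selector(env: EnvironmentGrid, depth_band):
    top, bottom = depth_band
    sel = (env.depth >= top) & (env.depth < bottom)
    if not sel.any():
        raise InvalidInputError(f"no depth levels in band {depth_band}")
    return sel


def habitat_volume(env: EnvironmentGrid, A_eco, E_eco_ref, dEdT,
                   phi_max=DEFAULT_PHI_MAX, depth_band=(0.0, 100.0),
                   t_ref=T_REF_DEFAULT) -> float:
    """Aerobic habitat volume (m^3): water with ``1 <= Phi <= phi_max``.

    Monthly grids average the monthly habitable volumes.
    """
    if phi_max <= 1:
        raise InvalidInputError("phi_max must be > 1")
    sel = _band_selector(env, depth_band)
    traits = TraitSet("_", A_eco=A_eco, E_eco_ref=E_eco_ref, dEdT=dEdT,
                      T_ref=t_ref)
    vol = env.cell_volume[sel]

    def _one(T, pO2):
        phi = metabolic_index(pO2, T, traits)
        return float(vol[(phi >= 1.0) & (phi <= phi_max)].sum())

    if env.months is None:
        return _one(env.T[sel], env.pO2[sel])
    vols = [_one(env.T[m][sel], env.pO2[m][sel]) for m in range(len(env.months))]
    return float(np.mean(vols))


@dataclass
class HabitatVolumeGrid:
    """Habitat volume evaluated over an (A_eco, E_eco) trait grid."""

    a_grid: np.ndarray      # 1/atm
    e_grid: np.ndarray      # eV
    dEdT: float             # eV/degC, scalar
    phi_max: float
    depth_band: tuple
    volume: np.ndarray      # m^3, shape (len(a_grid), len(e_grid))

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(range(self.a_grid.size), range(self.e_grid.size),
                             indexing="ij")
        return pd.DataFrame({
            "A_eco": self.a_grid[ii.ravel()],
            "E_eco": self.e_grid[jj.ravel()],
            "dEdT": self.dEdT,
            "phi_max": self.phi_max,
            "band_top_m": self.depth_band[0],
            "band_bottom_m": self.depth_band[1],
            "volume_m3": self.volume.ravel(),
        })


def habitat_volume_grid(env: EnvironmentGrid, a_grid, e_grid, dEdT=0.025,
                        phi_max=DEFAULT_PHI_MAX,
                        bands=((0.0, 100.0), (100.0, 1000.0)),
                        t_ref=T_REF_DEFAULT):
    """Habitat volume over a trait grid, per depth band.

    Pointwise evaluation (each entry equals :func:`habitat_volume` for
    that trait pair exactly).  The default dEdT of 0.025 eV/degC is the
    laboratory-derived central value.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    e_grid = np.asarray(e_grid, dtype=float)
    if a_grid.size == 0 or e_grid.size == 0:
        raise InvalidInputError("trait axes must be non-empty")
    out = []
    for band in bands:
        vol = np.empty((a_grid.size, e_grid.size))
        for i, a in enumerate(a_grid):
            for j, e in enumerate(e_grid):
                vol[i, j] = habitat_volume(env, a, e, dEdT, phi_max, band,
                                           t_ref)
        out.append(HabitatVolumeGrid(a_grid=a_grid, e_grid=e_grid, dEdT=dEdT,
                                     phi_max=phi_max, depth_band=tuple(band),
                                     volume=vol))
    return out


@dataclass(frozen=True)
class EdgeSensitivities:
    """Effective E_eco at the warm/cold range edges (eV)."""

    e_eco_warm: float
    e_eco_cold: float

    @property
    def delta_e_eco(self) -> float:
        return self.e_eco_warm - self.e_eco_cold


def edge_sensitivities(fit: FitResult) -> EdgeSensitivities:
    """E_eco at the warm and cold range edges.

    ``E_eco(T_edge) = E_eco_ref + dEdT * (T_edge - T_ref)`` with T_W and
    T_C the 95th/5th percentiles of inhabited temperatures, so that
    ``delta_e_eco == dEdT * (T_W - T_C)`` exactly.
    """
    t = fit.traits
    return EdgeSensitivities(
        e_eco_warm=t.E_eco_ref + t.dEdT * (fit.t_warm - t.T_ref),
        e_eco_cold=t.E_eco_ref + t.dEdT * (fit.t_cold - t.T_ref),
    )


def phi_max_ratio(fit: FitResult) -> float:
    """95th percentile of Phi over presence samples at the fitted traits.

    Because the fitted threshold is Phi = 1 (Phi is Phi_crit-normalized
    here), this is the species' Phi_max/Phi_crit: its O2 supply headroom
    above sustained needs.
    """
    if fit.presence_phi is None or len(fit.presence_phi) == 0:
        raise InvalidInputError("fit carries no presence Phi values")
    return float(np.percentile(fit.presence_phi, 95))


def e_phicrit(E_eco, E_o, species_eco=None, species_lab=None):
    """Temperature sensitivity of Phi_crit: ``E_eco - E_o`` (eV).

    The biogeographically diagnosed active sensitivity minus the
    laboratory resting sensitivity, per species.  When species ids are
    given they must match.
    """
    if species_eco is not None and species_lab is not None \
            and species_eco != species_lab:
        raise InvalidInputError(
            f"species mismatch: {species_eco!r} vs {species_lab!r}"
        )
    E_eco = np.asarray(E_eco, dtype=float)
    E_o = np.asarray(E_o, dtype=float)
    if not (np.all(np.isfinite(E_eco)) and np.all(np.isfinite(E_o))):
        raise InvalidInputError("E_eco and E_o must be finite")
    out = E_eco - E_o
    return float(out) if out.ndim == 0 else out


def e_phicrit_from_fas(fas, T, t_ref=T_REF_DEFAULT):
    """E_phicrit from FAS measured at multiple temperatures (eV).

    FAS (= MMR:RMR, a proxy for Phi_crit) is assumed Arrhenius in T, so
    the slope of ``ln(FAS)`` against ``x = -(1/k_B)(1/T_K - 1/Tref_K)``
    is its activation energy.  Least-squares slope; needs >= 2 distinct
    temperatures.
    """
    fas = np.asarray(fas, dtype=float)
    T = np.asarray(T, dtype=float)
    if fas.size != T.size or fas.size < 2:
        raise InvalidInputError("need FAS at >= 2 temperatures")
    if np.any(fas <= 0):
        raise InvalidInputError("FAS must be positive")
    x = -(1.0 / K_B) * (1.0 / (T + CELSIUS_OFFSET) - 1.0 / (t_ref + CELSIUS_OFFSET))
    if np.ptp(x) == 0:
        raise InvalidInputError("temperatures must be distinct")
    slope = np.polyfit(x, np.log(fas), 1)[0]
    return float(slope)


def latitudinal_summary(trait_table: pd.DataFrame, occurrences: pd.DataFrame,
                        band_width_deg=10.0,
                        columns=("A_eco", "E_eco_ref")) -> pd.DataFrame:
    """Per-latitude-band medians and deciles of species traits.

    Each species is placed at the median latitude of its occurrence
    records; bands tile [-90, 90].  Returns one row per (band, trait)
    with the band median and 10th/90th percentiles over species.
    """
    med_lat = occurrences.groupby("species")["decimalLatitude"].median()
    table = trait_table.set_index("species_id")
    joined = table.join(med_lat.rename("median_lat"), how="inner")
    if joined.empty:
        raise InvalidInputError("no species shared between traits and occurrences")
    edges = np.arange(-90.0, 90.0 + band_width_deg, band_width_deg)
    idx = np.clip(np.digitize(joined["median_lat"], edges) - 1, 0,
                  len(edges) - 2)
    rows = []
    for b in np.unique(idx):
        sub = joined[idx == b]
        for col in columns:
            vals = sub[col].to_numpy(dtype=float)
            rows.append({
                "band_south": edges[b],
                "band_north": edges[b + 1],
                "trait": col,
                "n_species": len(sub),
                "median": float(np.median(vals)),
                "p10": float(np.percentile(vals, 10)),
                "p90": float(np.percentile(vals, 90)),
            })
    return pd.DataFrame(rows)


def ks_two_sample(x, y):
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with ``D = sup |ECDF_x - ECDF_y|`` and the
    asymptotic Kolmogorov p-value using the effective sample size
    ``n*m/(n+m)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
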