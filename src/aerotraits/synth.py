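"""Synthetic ocean climatologies and species with known ground truth.

These generators stand in for the World Ocean Atlas climatology and
OBIS occurrence downloads so that every downstream stage (occupancy
building, trait fitting, diagnostics, phylogenetic signal) can be
exercised end to end with a known answer.  All generators are pure
functions of their parameters and a seed: reruns are bit-identical.

The synthetic ocean has the gross oxythermal structure that makes trait
diagnosis identifiable: a warm tropical surface (~29 degC) cooling
poleward (~-1.8 degC) and decaying with depth toward ~2 degC; surface
pO2 near atmospheric (slightly supersaturated in cold water); and a
low-latitude mid-depth oxygen minimum zone recovering at depth.
Seasonality, circulation and sampling-effort bias are deliberately not
emulated (occurrence sampling is volume-weighted and unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET, P_O2_DRY_AIR
from .errors import EmptyHabitatError, InvalidInputError
from .grid import EnvironmentGrid, cell_volumes
from .model import TraitSet, metabolic_index

__all__ = [
    "OceanParams",
    "make_ocean",
    "default_depth_edges",
    "o2conc_to_po2",
    "po2_to_o2conc",
    "SyntheticSpeciesTruth",
    "simulate_species",
    "draw_truth",
    "sample_species_set",
    "simulate_clade",
    "random_tree",
]


# ---------------------------------------------------------------------------
# Ocean generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OceanParams:
    """Tunable structure of the synthetic ocean (units in field names).

    The oxygen field carries the two features that make hypoxia traits
    diagnosable from biogeography, mirroring the real ocean: oxygen
    minimum zones whose core depth varies by basin (so low pO2 coexists
    with warm thermocline temperatures, as in the eastern tropical
    Pacific or Arabian Sea), and O2-depleted "aged" deep water (as in
    the deep North Pacific), so that most temperature classes offer a
    broad realized pO2 range.
    """

    t_tropical_c: float = 29.0      # surface max at the equator
    t_polar_c: float = -1.8         # surface min at the poles
    t_deep_c: float = 2.0           # deep-ocean asymptote
    thermocline_m: float = 300.0    # e-folding depth of the thermocline
    po2_surface_atm: float = 0.21   # tropical surface pO2
    supersaturation_atm: float = 0.015  # extra pO2 in cold surface water
    omz_po2_min_atm: float = 0.02   # pO2 at the OMZ core (tropics)
    omz_core_min_m: float = 150.0   # shallowest basin OMZ core depth
    omz_core_max_m: float = 500.0   # deepest basin OMZ core depth
    omz_width_m: float = 350.0      # OMZ vertical Gaussian width
    omz_lat_width_deg: float = 35.0 # OMZ latitudinal Gaussian width
    aged_amp: float = 0.55          # deep aged-water O2 depletion fraction
    aged_depth_m: float = 1400.0    # aged-water depletion core depth
    aged_width_m: float = 700.0     # aged-water vertical Gaussian width
    t_noise_c: float = 0.4          # amplitude of smooth zonal T structure
    po2_noise_atm: float = 0.01     # amplitude of smooth zonal pO2 structure
    land: bool = True               # carve an idealized continent
    seasonal_amp_c: float = 4.0     # surface seasonal cycle (monthly grids)


def default_depth_edges():
    """Standard-level layer interfaces (m), surface to 1000 m.

    The upper kilometre holds the habitat analysed here (the deeper
    bands add volume but little distinct oxythermal structure)."""
    return np.array([0, 50, 100, 200, 300, 400, 500, 700, 1000], dtype=float)


def _land_mask(lat, lon):
    """Idealized meridional continent plus a smaller landmass."""
    la, lo = np.meshgrid(lat, lon, indexing="ij")
    americas = (lo >= -80) & (lo < -40) & (np.abs(la) < 70)
    asia = (lo >= 95) & (lo < 140) & (la > -10) & (la < 60)
    return ~(americas | asia)  # True = ocean


def make_ocean(resolution_deg=2.0, depth_levels=None, params=None, seed=0,
               monthly=False) -> EnvironmentGrid:
    """Generate a latitude-depth structured synthetic ocean climatology.

    Parameters
    ----------
    resolution_deg : float
        Grid spacing; must divide 180 evenly.
    depth_levels : array-like or int, optional
        Layer interface depths (m, ascending from 0), or a count of
        equal layers spanning 0-2000 m.  Defaults to 10 standard layers.
    params : OceanParams, optional
    seed : int
        Seed for the smooth pseudo-random zonal structure.
    monthly : bool
        If True, emit a 12-month climatology with a sinusoidal surface
        seasonal cycle decaying over the top 100 m.
    """
    params = params or OceanParams()
    n_lat = 180.0 / resolution_deg
    if abs(n_lat - round(n_lat)) > 1e-9 or resolution_deg <= 0:
        raise InvalidInputError(
            f"resolution_deg must divide 180, got {resolution_deg}"
        )
    n_lat = int(round(n_lat))
    n_lon = 2 * n_lat
    lat_edges = np.linspace(-90.0, 90.0, n_lat + 1)
    lon_edges = np.linspace(-180.0, 180.0, n_lon + 1)
    lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])

    if depth_levels is None:
        depth_edges = default_depth_edges()
    elif np.ndim(depth_levels) == 0:
        depth_edges = np.linspace(0.0, 1000.0, int(depth_levels) + 1)
    else:
        depth_edges = np.asarray(depth_levels, dtype=float)
        if depth_edges[0] != 0 or np.any(np.diff(depth_edges) <= 0):
            raise InvalidInputError("depth edges must ascend from 0")
    depth = 0.5 * (depth_edges[:-1] + depth_edges[1:])

    rng = np.random.default_rng(seed)
    lat_r = np.deg2rad(lat)
    lon_r = np.deg2rad(lon)
    cos2 = np.cos(lat_r) ** 2

    # Temperature: poleward-cooling surface profile decaying with depth.
    t_surf = params.t_polar_c + (params.t_tropical_c - params.t_polar_c) * cos2
    decay = np.exp(-depth / params.thermocline_m)
    T = params.t_deep_c + (t_surf[None, :, None] - params.t_deep_c) * decay[:, None, None]

    # Smooth seeded zonal structure (few low-order harmonics) so that
    # cells at the same latitude/depth are not exactly degenerate.
    zdamp = np.exp(-depth / 1000.0)[:, None, None]
    struct = np.zeros((1, lat.size, lon.size))
    for k in (1, 2, 3):
        ph = rng.uniform(0, 2 * np.pi)
        ph2 = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0) / k
        struct += amp * np.sin(k * lon_r + ph)[None, None, :] * \
            np.cos(k * lat_r + ph2)[None, :, None]
    T = T + params.t_noise_c * struct * zdamp
    T = np.clip(T, -2.0, 30.0)

    # pO2: near-atmospheric surface, cold-water supersaturation, a
    # low-latitude oxygen minimum zone whose core depth varies zonally
    # (shallow warm-water OMZs in some basins), and aged deep water.
    p_surf = params.po2_surface_atm + params.supersaturation_atm * (1 - cos2)
    depletion_amp = 1.0 - params.omz_po2_min_atm / params.po2_surface_atm
    dep_lat = depletion_amp * np.exp(-(lat / params.omz_lat_width_deg) ** 2)
    zonal = 0.5 * (1 + np.sin(2 * lon_r + rng.uniform(0, 2 * np.pi)))
    core = params.omz_core_min_m + (params.omz_core_max_m - params.omz_core_min_m) \
        * 0.5 * (1 + np.sin(lon_r + rng.uniform(0, 2 * np.pi)))
    gz = np.exp(-(((depth[:, None] - core[None, :]) / params.omz_width_m) ** 2))
    omz = dep_lat[None, :, None] * gz[:, None, :] * (0.4 + 0.6 * zonal[None, None, :])
    aged = params.aged_amp * \
        np.exp(-(((depth - params.aged_depth_m) / params.aged_width_m) ** 2))[:, None, None] * \
        (0.3 + 0.7 * 0.5 * (1 + np.sin(lat_r)))[None, :, None]
    pO2 = p_surf[None, :, None] * (1 - np.clip(omz + aged, 0.0, 0.97))
    pO2 = pO2 + params.po2_noise_atm * struct * zdamp
    pO2 = np.clip(pO2, 0.0, None)

    ocean = _land_mask(lat, lon) if params.land else np.ones((lat.size, lon.size), bool)
    vol = cell_volumes(lat_edges, lon_edges, depth_edges)
    vol = np.where(ocean[None, :, :], vol, 0.0)

    months = None
    if monthly:
        months = np.arange(1, 13)
        cyc = np.cos(2 * np.pi * (months - 2.0) / 12.0)  # peak ~Feb (SH summer sign via -sin(lat))
        samp = params.seasonal_amp_c * np.sin(lat_r) * -1.0  # hemispheric phase flip
        sdamp = np.exp(-depth / 100.0)
        T = T[None] + cyc[:, None, None, None] * samp[None, None, :, None] * sdamp[None, :, None, None]
        T = np.clip(T, -2.0, 32.0)
        pO2 = np.broadcast_to(pO2[None], T.shape).copy()

    return EnvironmentGrid(lat=lat, lon=lon, depth=depth,
                           depth_edges=depth_edges, T=T, pO2=pO2,
                           cell_volume=vol, ocean_mask=ocean, months=months)


# ---------------------------------------------------------------------------
# O2 concentration <-> partial pressure adapter
# ---------------------------------------------------------------------------

# Garcia & Gordon (1992) O2 solubility fit to Benson & Krause data,
# umol/kg at saturation with water-saturated air at 1 atm.
_GG_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_GG_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_GG_C0 = -2.75915e-7


def _o2_saturation_umol_kg(T, S):
    T = np.asarray(T, dtype=float)
    if np.any(T < -3) or np.any(T > 40):
        raise InvalidInputError("solubility fit valid for T in [-3, 40] C")
    ts = np.log((298.15 - T) / (CELSIUS_OFFSET + T))
    a = _GG_A
    b = _GG_B
    ln_c = (a[0] + a[1] * ts + a[2] * ts ** 2 + a[3] * ts ** 3 + a[4] * ts ** 4
            + a[5] * ts ** 5
            + S * (b[0] + b[1] * ts + b[2] * ts ** 2 + b[3] * ts ** 3)
            + _GG_C0 * S ** 2)
    return np.exp(ln_c)


def o2conc_to_po2(conc_umol_kg, T, S=35.0):
    """Convert dissolved O2 (umol/kg) to partial pressure (atm).

    Henry's-law scaling against the Garcia & Gordon (1992) saturation
    concentration: ``pO2 = conc / C_sat(T, S) * 0.20946 atm``.  Linear
    (hence strictly increasing) in concentration at fixed T, S.
    """
    conc = np.asarray(conc_umol_kg, dtype=float)
    if np.any(conc < 0):
        raise InvalidInputError("concentration must be >= 0")
    out = conc / _o2_saturation_umol_kg(T, S) * P_O2_DRY_AIR
    return float(out) if np.ndim(conc_umol_kg) == 0 and np.ndim(T) == 0 else out


def po2_to_o2conc(po2_atm, T, S=35.0):
    """Inverse of :func:`o2conc_to_po2` (exact round trip)."""
    po2 = np.asarray(po2_atm, dtype=float)
    if np.any(po2 < 0):
        raise InvalidInputError("pO2 must be >= 0")
    out = po2 / P_O2_DRY_AIR * _o2_saturation_umol_kg(T, S)
    return float(out) if np.ndim(po2_atm) == 0 and np.ndim(T) == 0 else out


# ---------------------------------------------------------------------------
# Species occurrence generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpeciesTruth:
    """Ground truth for one synthetic species."""

    species_id: str
    traits: TraitSet
    phi_max: float = 3.0
    n_presence: int = 500
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.noise_rate < 0.5):
            raise InvalidInputError("noise_rate must be in [0, 0.5)")
        if self.phi_max <= 1:
            raise InvalidInputError("phi_max must be > 1")


def habitat_mask(env: EnvironmentGrid, traits: TraitSet, phi_max: float):
    """Boolean (depth, lat, lon) mask of cells with 1 <= Phi <= phi_max."""
    T, pO2 = env.annual()
    phi = metabolic_index(pO2, T, traits)
    return (env.cell_volume > 0) & (phi >= 1.0) & (phi <= phi_max)


def simulate_species(env: EnvironmentGrid, truth: SyntheticSpeciesTruth) -> pd.DataFrame:
    """Sample occurrence records from a species' Phi-defined habitat.

    Presence cells are drawn with replacement, with probability
    proportional to cell volume, from the habitat
    ``1 <= Phi(truth) <= phi_max``.  Each record is independently
    flipped, with probability ``noise_rate``, to a uniformly random
    non-habitat ocean cell (the simplest misdetection model).  Records
    are Darwin Core-like rows at cell centers.
    """
    hab = habitat_mask(env, truth.traits, truth.phi_max)
    if not hab.any():
        raise EmptyHabitatError(
            f"no habitable cells for {truth.species_id!r} with traits "
            f"A_eco={truth.traits.A_eco:.4g}, E_eco_ref={truth.traits.E_eco_ref:.4g}, "
            f"dEdT={truth.traits.dEdT:.4g}, phi_max={truth.phi_max:.4g}"
        )
    rng = np.random.default_rng(truth.seed)
    flat_hab = np.flatnonzero(hab.ravel())
    w = env.cell_volume.ravel()[flat_hab]
    draws = rng.choice(flat_hab, size=truth.n_presence, p=w / w.sum())
    if truth.noise_rate > 0:
        non_hab = np.flatnonzero((env.cell_volume > 0).ravel() & ~hab.ravel())
        flip = rng.random(truth.n_presence) < truth.noise_rate
        if flip.any() and non_hab.size:
            draws = draws.copy()
            draws[flip] = rng.choice(non_hab, size=int(flip.sum()))
    iz, iy, ix = np.unravel_index(draws, env.cell_volume.shape)
    return pd.DataFrame(
        {
            "species": truth.species_id,
            "decimalLatitude": env.lat[iy],
            "decimalLongitude": env.lon[ix],
            "depth": env.depth[iz],
            "month": pd.array([pd.NA] * len(draws), dtype="Int64"),
        }
    )


def draw_truth(rng, species_id, a_range=(2.0, 50.0), e_range=(-0.5, 1.0),
               dedt_mean=0.05, dedt_sd=0.03, dedt_clip=(0.0, 0.12),
               phi_max=1.4, n_presence=500, noise_rate=0.05,
               seed=0) -> SyntheticSpeciesTruth:
    """Draw a random species truth from the observed trait distribution.

    A_eco is log-uniform over the bulk of diagnosed tolerances, E_eco_ref
    uniform over the bulk of diagnosed sensitivities, and dEdT normal
    with the reported mean 0.05 and s.d. 0.03 eV/degC (clipped to the
    physical search range).  phi_max defaults to 1.4, the median
    occupied Phi headroom above threshold across species.
    """
    a = float(np.exp(rng.uniform(np.log(a_range[0]), np.log(a_range[1]))))
    e = float(rng.uniform(*e_range))
    d = float(np.clip(rng.normal(dedt_mean, dedt_sd), *dedt_clip))
    traits = TraitSet(species_id, A_eco=a, E_eco_ref=e, dEdT=d)
    return SyntheticSpeciesTruth(species_id, traits, phi_max=phi_max,
                                 n_presence=n_presence, noise_rate=noise_rate,
                                 seed=seed)


def sample_species_set(env: EnvironmentGrid, n_species, seed,
                       min_habitat_cells=30, max_tries=200, **truth_kwargs):
    """Draw ``n_species`` truths with viable habitats plus their records.

    Truths whose habitat is empty or smaller than ``min_habitat_cells``
    (too few occupiable cells to ever pass the occupancy min-cells gate)
    are redrawn from the same stream; fully deterministic given seed.

    Returns ``(truths, occurrences)`` with occurrences concatenated.
    """
    rng = np.random.default_rng(seed)
    truths, frames = [], []
    i = 0
    while len(truths) < n_species:
        i += 1
        if i > max_tries * n_species:
            raise RuntimeError("could not draw enough viable species")
        sid = f"sp{len(truths) + 1:04d}"
        truth = draw_truth(rng, sid, seed=int(rng.integers(2 ** 31)),
                           **truth_kwargs)
        hab = habitat_mask(env, truth.traits, truth.phi_max)
        if hab.sum() < min_habitat_cells:
            continue
        truths.append(truth)
        frames.append(simulate_species(env, truth))
    return truths, pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Phylogenetic trait simulation
# ---------------------------------------------------------------------------

def simulate_clade(tree, sigma2, lambda_true, root_value, seed):
    """Draw tip trait values from the lambda-scaled Brownian model.

    Values are multivariate normal with mean ``root_value`` and
    covariance ``sigma2 * C_lambda`` where ``C`` is the shared
    root-to-MRCA path-length matrix of the tree and ``C_lambda`` has its
    off-diagonal entries multiplied by ``lambda_true``.  Returns a
    pandas Series indexed by tip label.
    """
    from .phylo import phylo_covariance

    if sigma2 < 0:
        raise InvalidInputError("sigma2 must be >= 0")
    labels, C = phylo_covariance(tree, lambda_true)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        return pd.Series(np.full(len(labels), float(root_value)), index=labels)
    cov = sigma2 * C
    try:
        L = np.linalg.cholesky(cov + 0.0)
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError(
            "tip covariance is not positive definite"
        ) from exc
    z = rng.standard_normal(len(labels))
    return pd.Series(root_value + L @ z, index=labels)


def random_tree(n_tips, seed, rho=0.4):
    """Random rooted binary tree over ``n_tips`` labelled species.

    Topology from successive random joins; branch lengths from the
    Grafen descendant-tip transform with exponent ``rho`` (or raw
    topology if ``rho`` is None).
    """
    import dendropy

    from .phylo import grafen_branch_lengths

    if n_tips < 2:
        raise InvalidInputError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(label=f"sp{i + 1:04d}")
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    if rho is not None:
        tree = grafen_branch_lengths(tree, rho=rho)
    return tree
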