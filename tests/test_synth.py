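"""Synthetic ocean and species generators."""

import numpy as np
import pytest
from scipy import stats

import aerotraits as at
from aerotraits.constants import EARTH_RADIUS_M
from aerotraits.errors import EmptyHabitatError, InvalidInputError
from aerotraits.model import metabolic_index
from aerotraits.synth import (OceanParams, default_depth_edges, habitat_mask,
                              o2conc_to_po2, po2_to_o2conc, random_tree)


def test_make_ocean_deterministic():
    a = at.make_ocean(6.0, seed=1)
    b = at.make_ocean(6.0, seed=1)
    assert np.array_equal(a.T, b.T)
    assert np.array_equal(a.pO2, b.pO2)
    assert np.array_equal(a.cell_volume, b.cell_volume)
    c = at.make_ocean(6.0, seed=2)
    assert not np.array_equal(a.T, c.T)


def test_make_ocean_bounds_and_structure(ocean6):
    env = ocean6
    assert env.T.min() >= -2.0 and env.T.max() <= 30.0
    assert env.pO2.min() >= 0.0
    assert np.all(env.cell_volume >= 0)
    assert np.all(env.cell_volume[:, ~env.ocean_mask] == 0)
    surf = env.T[0]
    tropics = np.abs(env.lat) < 10
    poles = np.abs(env.lat) > 80
    assert surf[tropics].max() == surf.max()
    assert surf[poles].min() == surf.min()
    # mid-depth oxygen minimum in the tropics
    itrop = np.argmin(np.abs(env.lat))
    profile = env.pO2[:, itrop, :].min(axis=1)
    assert profile.min() < 0.05
    assert np.argmin(profile) not in (0, len(profile) - 1)


def test_make_ocean_invalid_resolution():
    with pytest.raises(InvalidInputError):
        at.make_ocean(7.0)


def test_ocean_volume_matches_spherical_shells():
    """All-ocean grid volume equals the analytic spherical-shell value."""
    env = at.make_ocean(6.0, seed=0, params=OceanParams(land=False))
    depth_total = default_depth_edges()[-1]
    analytic = 4 * np.pi * EARTH_RADIUS_M ** 2 * depth_total
    assert env.total_volume() == pytest.approx(analytic, rel=1e-3)


def test_o2_conversion_properties():
    assert o2conc_to_po2(0.0, 10.0) == 0.0
    conc = np.linspace(0, 400, 41)
    po2 = o2conc_to_po2(conc, 12.0)
    assert np.all(np.diff(po2) > 0)
    # round trip
    back = po2_to_o2conc(o2conc_to_po2(150.0, 4.0), 4.0)
    assert back == pytest.approx(150.0, rel=1e-10)
    # saturated water at 1 atm moist air sits near the dry-air pO2
    assert o2conc_to_po2(po2_to_o2conc(0.20946, 15.0), 15.0) == pytest.approx(
        0.20946, rel=1e-12)
    with pytest.raises(InvalidInputError):
        o2conc_to_po2(100.0, 45.0)
    with pytest.raises(InvalidInputError):
        o2conc_to_po2(-1.0, 10.0)


def test_simulate_species_noiseless_records_in_habitat(ocean6, demo_species):
    truth, occ = demo_species
    phi = []
    for _, row in occ.iterrows():
        iy = np.argmin(np.abs(ocean6.lat - row.decimalLatitude))
        ix = np.argmin(np.abs(ocean6.lon - row.decimalLongitude))
        iz = np.argmin(np.abs(ocean6.depth - row.depth))
        phi.append(metabolic_index(ocean6.pO2[iz, iy, ix],
                                   ocean6.T[iz, iy, ix], truth.traits))
    phi = np.array(phi)
    assert np.all((phi >= 1.0) & (phi <= truth.phi_max))


def test_simulate_species_deterministic(ocean6, demo_species):
    truth, occ = demo_species
    again = at.simulate_species(ocean6, truth)
    assert occ.equals(again)


def test_simulate_species_noise_fraction(ocean6):
    truth = at.SyntheticSpeciesTruth(
        "n", at.TraitSet("n", 8.0, 0.3, 0.02), phi_max=1.4,
        n_presence=2000, noise_rate=0.05, seed=11)
    occ = at.simulate_species(ocean6, truth)
    hab = habitat_mask(ocean6, truth.traits, truth.phi_max)
    out = 0
    for _, row in occ.iterrows():
        iy = np.argmin(np.abs(ocean6.lat - row.decimalLatitude))
        ix = np.argmin(np.abs(ocean6.lon - row.decimalLongitude))
        iz = np.argmin(np.abs(ocean6.depth - row.depth))
        out += not hab[iz, iy, ix]
    lo, hi = stats.binom.interval(0.99, 2000, 0.05)
    assert lo <= out <= hi


def test_simulate_species_volume_weighting(ocean6):
    """Per-cell sampling frequencies converge to volume shares."""
    truth = at.SyntheticSpeciesTruth(
        "v", at.TraitSet("v", 8.0, 0.3, 0.02), phi_max=1.4,
        n_presence=50_000, noise_rate=0.0, seed=5)
    occ = at.simulate_species(ocean6, truth)
    hab = habitat_mask(ocean6, truth.traits, truth.phi_max)
    idx = {}
    for z, y, x in zip(*np.nonzero(hab)):
        idx[(ocean6.depth[z], ocean6.lat[y], ocean6.lon[x])] = (z, y, x)
    counts = occ.groupby(["depth", "decimalLatitude", "decimalLongitude"]).size()
    obs = np.zeros(len(idx))
    vols = np.zeros(len(idx))
    for i, (key, cell) in enumerate(idx.items()):
        obs[i] = counts.get((key[0], key[1], key[2]), 0)
        vols[i] = ocean6.cell_volume[cell]
    expected = vols / vols.sum() * obs.sum()
    # pool tiny-expectation cells for a valid chi-square
    big = expected >= 5
    obs_p = np.append(obs[big], obs[~big].sum())
    exp_p = np.append(expected[big], expected[~big].sum())
    _, p = stats.chisquare(obs_p, exp_p)
    assert p > 0.01


def test_simulate_species_empty_habitat_error(ocean6):
    truth = at.SyntheticSpeciesTruth(
        "e", at.TraitSet("e", 0.5, 2.0, 0.12), phi_max=1.01, seed=1)
    with pytest.raises(EmptyHabitatError) as exc:
        at.simulate_species(ocean6, truth)
    assert "A_eco" in str(exc.value)


def test_simulate_clade_degenerate_cases():
    tree = random_tree(8, seed=3)
    flat = at.simulate_clade(tree, sigma2=0.0, lambda_true=1.0,
                             root_value=2.5, seed=0)
    assert np.allclose(flat.values, 2.5)
    # lambda = 0: tips are independent with variance sigma2 * depth
    tree3 = random_tree(3, seed=1)
    draws = np.array([at.simulate_clade(tree3, 1.0, 0.0, 0.0, seed=s).values
                      for s in range(4000)])
    cov = np.cov(draws.T)
    assert np.all(np.abs(cov[~np.eye(3, dtype=bool)]) < 0.1)


def test_simulate_clade_covariance_matches_closed_form():
    from aerotraits.phylo import phylo_covariance
    tree = random_tree(3, seed=7)
    lam, s2 = 0.6, 1.3
    _, C = phylo_covariance(tree, lam)
    draws = np.array([at.simulate_clade(tree, s2, lam, 0.0, seed=s).values
                      for s in range(5000)])
    cov = np.cov(draws.T)
    assert np.allclose(cov, s2 * C, rtol=0.05, atol=0.05)


def test_random_tree_deterministic():
    a = at.random_tree(20, seed=9)
    b = at.random_tree(20, seed=9)
    from aerotraits.phylo import write_newick
    assert write_newick(a) == write_newick(b)
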