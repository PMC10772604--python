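"""Habitat volumes, range-edge sensitivities and summary statistics."""

import numpy as np
import pandas as pd
import pytest

import aerotraits as at
from aerotraits.diagnostics import (EdgeSensitivities, e_phicrit,
                                    e_phicrit_from_fas, edge_sensitivities,
                                    habitat_volume, habitat_volume_grid,
                                    ks_two_sample, latitudinal_summary,
                                    phi_max_ratio)
from aerotraits.errors import InvalidInputError
from aerotraits.fitting import FitResult
from aerotraits.grid import EnvironmentGrid
from aerotraits.model import TraitSet
from .oracles import habitat_volume_loop, ks_statistic_enumerated


@pytest.fixture(scope="module")
def toy_grid():
    """4 lat x 4 lon x 2 depth grid with integer volumes (exact sums)."""
    lat = np.array([-45.0, -15.0, 15.0, 45.0])
    lon = np.array([-135.0, -45.0, 45.0, 135.0])
    depth = np.array([25.0, 150.0])
    rng = np.random.default_rng(8)
    T = rng.uniform(0, 28, (2, 4, 4))
    pO2 = rng.uniform(0.01, 0.22, (2, 4, 4))
    vol = rng.integers(1, 9, (2, 4, 4)).astype(float)
    return EnvironmentGrid(lat=lat, lon=lon, depth=depth,
                           depth_edges=np.array([0.0, 50.0, 250.0]),
                           T=T, pO2=pO2, cell_volume=vol,
                           ocean_mask=np.ones((4, 4), bool))


def test_habitat_volume_matches_loop_oracle(toy_grid):
    for a, e, d in [(8.0, 0.3, 0.02), (2.0, -0.2, 0.0), (30.0, 0.8, 0.05)]:
        got = habitat_volume(toy_grid, a, e, d, phi_max=1.4,
                             depth_band=(0, 250))
        want = habitat_volume_loop(toy_grid, a, e, d, 1.4, (0, 250))
        assert got == want


def test_habitat_volume_degenerate_cases(toy_grid):
    # traits with Phi < 1 everywhere -> zero volume
    assert habitat_volume(toy_grid, 1e-6, 0.0, 0.0, 1.4, (0, 250)) == 0.0
    with pytest.raises(InvalidInputError):
        habitat_volume(toy_grid, 8.0, 0.3, 0.0, 1.4, (500, 900))
    with pytest.raises(InvalidInputError):
        habitat_volume(toy_grid, 8.0, 0.3, 0.0, phi_max=0.9)


def test_habitat_volume_conservation(toy_grid):
    """Habitable + sub-threshold + super-band volumes sum exactly."""
    a, e, d, pm = 8.0, 0.3, 0.02, 1.4
    band = (0, 250)
    tr = TraitSet("", a, e, d)
    from aerotraits.model import metabolic_index
    phi = metabolic_index(toy_grid.pO2, toy_grid.T, tr)
    vol = toy_grid.cell_volume
    habitable = habitat_volume(toy_grid, a, e, d, pm, band)
    sub = vol[phi < 1].sum()
    sup = vol[phi > pm].sum()
    assert habitable + sub + sup == toy_grid.total_volume(band)


def test_habitat_volume_monotone_in_A_without_upper_band(toy_grid):
    a_vals = np.geomspace(0.5, 100, 12)
    vols = [habitat_volume(toy_grid, a, 0.3, 0.02, np.inf, (0, 250))
            for a in a_vals]
    assert np.all(np.diff(vols) >= 0)


def test_habitat_volume_grid_consistency(toy_grid):
    a_grid = np.geomspace(1, 30, 4)
    e_grid = np.linspace(-0.2, 0.8, 3)
    grids = habitat_volume_grid(toy_grid, a_grid, e_grid, dEdT=0.025,
                                phi_max=1.4, bands=[(0, 250)])
    g = grids[0]
    for i, a in enumerate(a_grid):
        for j, e in enumerate(e_grid):
            assert g.volume[i, j] == habitat_volume(
                toy_grid, a, e, 0.025, 1.4, (0, 250))
    frame = g.to_frame()
    assert len(frame) == 12 and frame["volume_m3"].min() >= 0


def test_habitat_volume_depth_band_slope_change(ocean6):
    """The A-E relationship of available habitat changes sign with
    depth: in the cool 100-1000 m band the best-provisioned A falls
    monotonically as E rises, while in the warm upper 100 m the
    high-E optimum jumps to large A (warm surface strata)."""
    a_grid = np.geomspace(0.5, 100, 31)

    def argmax_a(E, band):
        vols = [habitat_volume(ocean6, a, E, 0.025, 1.4, band)
                for a in a_grid]
        return a_grid[np.argmax(vols)]

    e_vals = [-0.8, -0.4, 0.0, 0.4, 0.8, 1.2]
    deep = [argmax_a(E, (100, 1000)) for E in e_vals]
    assert np.all(np.diff(deep) < 0)
    assert argmax_a(1.2, (0, 100)) > deep[-1]


def _fit_stub(e_ref, dedt, t_c, t_w, phi=None):
    return FitResult(species_id="s",
                     traits=TraitSet("s", 5.0, e_ref, dedt),
                     f1=0.9, tp=1, fp=0, fn=0, tn=1,
                     t_cold=t_c, t_warm=t_w, phi_max=1.2,
                     n_presence_cells=10,
                     presence_phi=np.asarray(phi if phi is not None else [1.0]))


def test_edge_sensitivities():
    es = edge_sensitivities(_fit_stub(0.19, 0.05, 12.0, 20.0))
    assert es.e_eco_warm == pytest.approx(0.44)
    assert es.e_eco_cold == pytest.approx(0.19 + 0.05 * (12 - 15))
    # delta identity is exact
    assert es.delta_e_eco == pytest.approx(0.05 * 8.0, abs=1e-15)
    flat = edge_sensitivities(_fit_stub(0.3, 0.0, 2.0, 25.0))
    assert flat.delta_e_eco == 0.0
    # mean dEdT 0.05 over an 8 K range gives ~0.4 eV
    assert EdgeSensitivities(0.4, 0.0).delta_e_eco == pytest.approx(0.4)


def test_phi_max_ratio():
    assert phi_max_ratio(_fit_stub(0, 0, 0, 1, phi=[1.0] * 7)) == 1.0
    vals = np.arange(1.0, 2.01, 0.1)
    assert phi_max_ratio(_fit_stub(0, 0, 0, 1, phi=vals)) == pytest.approx(
        np.percentile(vals, 95))
    assert phi_max_ratio(_fit_stub(0, 0, 0, 1, phi=[2.0, 3.0])) > 1.0


def test_e_phicrit():
    assert e_phicrit(0.19, 0.34) == pytest.approx(-0.15)
    assert e_phicrit(0.5, 0.5) == 0.0
    with pytest.raises(InvalidInputError):
        e_phicrit(0.2, 0.3, species_eco="a", species_lab="b")


def test_e_phicrit_from_fas_two_point():
    """Two-temperature Arrhenius slope of ln(FAS), hand-checked."""
    from aerotraits.constants import CELSIUS_OFFSET, K_B
    x = [-(1 / K_B) * (1 / (t + CELSIUS_OFFSET) - 1 / (15 + CELSIUS_OFFSET))
         for t in (10.0, 20.0)]
    expected = (np.log(3) - np.log(4)) / (x[1] - x[0])
    got = e_phicrit_from_fas([4.0, 3.0], [10.0, 20.0])
    assert got == pytest.approx(expected, rel=1e-12)
    assert got < 0
    with pytest.raises(InvalidInputError):
        e_phicrit_from_fas([4.0], [10.0])


def _trait_table(rows):
    return pd.DataFrame(rows, columns=["species_id", "A_eco", "E_eco_ref"])


def test_latitudinal_summary():
    occ = pd.DataFrame({
        "species": ["a"] * 3 + ["b"] * 2,
        "decimalLatitude": [59.0, 60.0, 61.0, 5.0, 7.0],
    })
    traits = _trait_table([("a", 4.0, 0.8), ("b", 20.0, 0.1)])
    out = latitudinal_summary(traits, occ, band_width_deg=10.0)
    band_a = out[(out.band_south == 60.0) & (out.trait == "A_eco")]
    assert band_a["median"].iloc[0] == 4.0  # single species is the median
    # duplicating one species' records leaves medians unchanged
    occ2 = pd.concat([occ, occ[occ.species == "a"]], ignore_index=True)
    out2 = latitudinal_summary(traits, occ2, band_width_deg=10.0)
    pd.testing.assert_frame_equal(out, out2)


def test_latitudinal_summary_recovers_monotone_gradient():
    rng = np.random.default_rng(5)
    rows, occ_rows = [], []
    for i, lat in enumerate(np.arange(-75, 80, 10.0)):
        a = 30.0 * np.cos(np.deg2rad(lat)) + 2.0  # equatorward increase
        rows.append((f"s{i}", a, 0.2))
        for _ in range(5):
            occ_rows.append((f"s{i}", lat + rng.uniform(-2, 2)))
    out = latitudinal_summary(
        _trait_table(rows),
        pd.DataFrame(occ_rows, columns=["species", "decimalLatitude"]),
        band_width_deg=10.0)
    a_med = out[out.trait == "A_eco"].sort_values("band_south")["median"].values
    peak = np.argmax(a_med)
    assert np.all(np.diff(a_med[:peak + 1]) >= 0)
    assert np.all(np.diff(a_med[peak:]) <= 0)


def test_ks_two_sample():
    x = np.array([0.1, 0.4, 0.7, 0.9])
    assert ks_two_sample(x, x) == (0.0, 1.0)
    d, p = ks_two_sample([0.0, 1.0], [10.0, 11.0])
    assert d == 1.0 and 0 <= p <= 1
    # matches exhaustive enumeration at n = m = 4
    y = np.array([0.2, 0.3, 0.8, 1.5])
    d, _ = ks_two_sample(x, y)
    assert d == pytest.approx(ks_statistic_enumerated(x, y), abs=1e-12)
    # symmetry
    assert ks_two_sample(x, y) == ks_two_sample(y, x)
    with pytest.raises(InvalidInputError):
        ks_two_sample([], [1.0])


def test_ks_p_decreases_with_d():
    base = np.linspace(0, 1, 30)
    ps = []
    for shift in (0.0, 0.3, 0.8, 1.5):
        d, p = ks_two_sample(base, base + shift)
        ps.append(p)
    assert all(a >= b for a, b in zip(ps, ps[1:]))
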