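import numpy as np
import pytest

import aerotraits as at
from aerotraits.occupancy import OccupancyDataset


@pytest.fixture(scope="session")
def ocean6():
    """Coarse (6 deg) synthetic ocean shared by fast tests."""
    return at.make_ocean(6.0, seed=2)


@pytest.fixture(scope="session")
def ocean2():
    """The 2 deg ocean used by the recovery studies."""
    return at.make_ocean(2.0, seed=1)


@pytest.fixture(scope="session")
def demo_species(ocean6):
    """One synthetic species with known traits on the coarse ocean."""
    truth = at.SyntheticSpeciesTruth(
        "demo", at.TraitSet("demo", A_eco=8.0, E_eco_ref=0.3, dEdT=0.02),
        phi_max=1.4, n_presence=500, noise_rate=0.0, seed=3,
    )
    occ = at.simulate_species(ocean6, truth)
    return truth, occ


def make_dataset(T, pO2, presence, species_id="x", weight=None):
    """Hand-build an occupancy dataset from parallel arrays."""
    T = np.asarray(T, float)
    presence = np.asarray(presence, bool)
    return OccupancyDataset(
        species_id=species_id,
        T=T,
        pO2=np.asarray(pO2, float),
        presence=presence,
        weight=np.ones(len(T)) if weight is None else np.asarray(weight, float),
        n_presence_cells=int(presence.sum()),
    )
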