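import numpy as np
import pytest

from pcpotts import lattice as L
from pcpotts.lattice import (CompartmentRegistry, ContactEnergyModel, Lattice,
                             NoiseModel)


@pytest.fixture
def random_lattice():
    """Small random multi-cell configuration for energy/dynamics tests.

    6 cells x 4 compartments with random labels scattered over a 20x20
    torus plus some medium — deliberately far from equilibrium so that
    proposals probe every branch of the energy computation.
    """
    def make(seed=0, n_cells=6, size=20, medium=True):
        rng = np.random.default_rng(seed)
        lat = Lattice(size, size)
        reg = CompartmentRegistry()
        ids = [0] if medium else []
        for cl in range(n_cells):
            for t in (L.PROX, L.DIST, L.LAT, L.CYTO):
                ids.append(reg.new_compartment(t, cl, float(rng.integers(5, 20)),
                                               2.0))
        lat.sites[:] = rng.choice(ids, size=size * size)
        lat.recount_volumes(reg)
        return lat, reg

    return make


@pytest.fixture
def model():
    return ContactEnergyModel.autonomous()


@pytest.fixture
def noise():
    return NoiseModel(10.0, 42)
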