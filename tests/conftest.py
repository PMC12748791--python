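import numpy as np
import pytest

from elevatorfep.colvars import CVReference, DomainSelection
from elevatorfep.toy_systems import (PotentialModel, make_double_well,
                                     make_elevator_bead_model,
                                     make_two_basin_2d)


@pytest.fixture(scope="session")
def double_well():
    """Symmetric 1D double well: barrier 5 kcal/mol, minima at ±2 Å."""
    return make_double_well(barrier=5.0, separation=4.0)


@pytest.fixture(scope="session")
def two_basin():
    """Default 2D elevator landscape with IF basin ~1 kcal/mol above OF."""
    return make_two_basin_2d(asymmetry=1.0, confinement=2.0)


@pytest.fixture(scope="session")
def bead_system():
    return make_elevator_bead_model(seed=3)


@pytest.fixture(scope="session")
def bead_refs(bead_system):
    return CVReference.from_bead_system(bead_system)


@pytest.fixture(scope="session")
def bead_sel(bead_system):
    return DomainSelection(bead_system.scaffold_indices(),
                           bead_system.td_indices())


def flat_model(dim=1, temperature=310.0, guard=1e6):
    """Zero-potential model (free diffusion) for closed-form checks."""
    return PotentialModel(
        dimensionality=dim,
        energy=lambda x: np.zeros(np.asarray(x, dtype=float).shape[:-1]
                                  if np.asarray(x).ndim > 1 else ()),
        gradient=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        temperature=temperature,
        params={"basins": np.zeros((1, dim)), "domain_guard": guard})


def harmonic_model(k=1.0, dim=1, temperature=310.0):
    """Isotropic harmonic well U = k|x|^2/2."""
    return PotentialModel(
        dimensionality=dim,
        energy=lambda x: 0.5 * k * (np.asarray(x, dtype=float) ** 2).sum(axis=-1),
        gradient=lambda x: k * np.asarray(x, dtype=float),
        temperature=temperature,
        params={"basins": np.zeros((1, dim)), "domain_guard": 1e6})
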