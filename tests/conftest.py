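import numpy as np
import pytest

from csrefine.geometry import InternalCoordinates, build_backbone
from csrefine.synthetic_data import (
    make_experiment, make_grid_predictor, make_random_coil_fixture,
    generate_reference_structure,
)


@pytest.fixture(scope="session")
def helix10():
    """Ideal 10-residue poly-alanine alpha helix."""
    seq = ["ALA"] * 10
    return build_backbone(seq, InternalCoordinates.ideal(seq, phi=-57.0, psi=-47.0))


@pytest.fixture(scope="session")
def predictor():
    return make_grid_predictor(seed=7)


@pytest.fixture(scope="session")
def random_coil():
    return make_random_coil_fixture(seed=11)


@pytest.fixture(scope="session")
def small_experiment():
    """A 20-residue closed-loop experiment shared by sampler tests."""
    return make_experiment(n_residues=20, motif="mixed", seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_internal(rng, sequence):
    """Random but buildable internal coordinates for round-trip tests."""
    n = len(sequence)
    ic = InternalCoordinates.ideal(sequence)
    ic.phi[1:] = rng.uniform(-179.0, 179.0, n - 1)
    ic.psi[:-1] = rng.uniform(-179.0, 179.0, n - 1)
    ic.omega[1:] = rng.uniform(160.0, 179.0, n - 1)
    ic.ang_n_ca_c[:] = rng.uniform(105.0, 118.0, n)
    ic.ang_ca_c_n[:-1] = rng.uniform(110.0, 122.0, n - 1)
    ic.ang_c_n_ca[:-1] = rng.uniform(115.0, 128.0, n - 1)
    for i in range(n):
        ic.chi[i] = rng.uniform(-179.0, 179.0, len(ic.chi[i]))
    return ic
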