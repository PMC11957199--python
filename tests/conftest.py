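import numpy as np
import pytest

from sqd_binder import random_hamiltonian, single_reference_hamiltonian


@pytest.fixture(scope="session")
def ham4():
    """Moderately correlated random (4e,4o) fixture; d = 36."""
    return random_hamiltonian(4, 2, 2, seed=7, scale=0.5)


@pytest.fixture(scope="session")
def ham3():
    """Open-shell random (3e,3o) fixture; d = 9."""
    return random_hamiltonian(3, 2, 1, seed=11)


@pytest.fixture(scope="session")
def single_ref5():
    """Single-reference-like (4e,5o) fixture for extrapolation tests."""
    return single_reference_hamiltonian(5, 2, 2, seed=1)


@pytest.fixture(scope="session")
def h2_like():
    """Minimal-basis H2-style two-orbital Hamiltonian (physical integrals)."""
    from sqd_binder import ActiveSpaceHamiltonian
    from sqd_binder.hamiltonian_io import _set_eri

    h = np.diag([-1.25, -0.47])
    eri = np.zeros((2, 2, 2, 2))
    _set_eri(eri, 0, 0, 0, 0, 0.675)
    _set_eri(eri, 1, 1, 1, 1, 0.697)
    _set_eri(eri, 0, 0, 1, 1, 0.664)
    _set_eri(eri, 0, 1, 1, 0, 0.181)
    return ActiveSpaceHamiltonian(2, 1, 1, 0.71, h, eri)


@pytest.fixture(scope="session")
def water_dimer_geometry():
    """Hydrogen-bonded water-dimer-like test geometry.

    Synthetic stand-in coordinates (idealized monomer geometry, O-O
    separation 2.9 Angstrom along z), not the benchmark-database
    equilibrium structure.
    """
    from sqd_binder import Geometry

    return Geometry(
        [
            ("O", 0.000, 0.000, 0.000),
            ("H", 0.757, 0.586, 0.000),
            ("H", -0.757, 0.586, 0.000),
            ("O", 0.000, 0.000, 2.900),
            ("H", 0.757, 0.586, 2.900),
            ("H", -0.757, 0.586, 2.900),
        ],
        metadata="synthetic water dimer stand-in",
    )
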