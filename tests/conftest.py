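"""Shared fixtures: the 1D bulk-solvent stage is expensive (~1 min for the
aqueous salt solvents), so converged susceptibilities are session-scoped and
additionally memoized inside crystalrism.fixtures.build_solvent."""

import numpy as np
import pytest

from crystalrism.fixtures import build_solvent, ideal_gas_solvent


@pytest.fixture(scope="session")
def lj_solvent():
    """Single-site LJ fluid at rho*sigma^3 = 0.4, HNC."""
    return build_solvent("lj", closure="hnc", n_points=8192, rho_sigma3=0.4)


@pytest.fixture(scope="session")
def salt_solvent():
    """Aqueous 1 M 1:1 salt (water-like 3-site + 2 ions), KH."""
    return build_solvent("salt", closure="kh", n_points=8192, molar=1.0)


@pytest.fixture(scope="session")
def dilute_salt_solvent():
    """Aqueous 0.1 M 1:1 salt, KH (used by the finite-size series)."""
    return build_solvent("salt", closure="kh", n_points=8192, molar=0.1)


@pytest.fixture(scope="session")
def water_solvent():
    """Pure 3-site water-like solvent, KH, short grid (unit tests only)."""
    return build_solvent("water", closure="kh", n_points=4096)


@pytest.fixture(scope="session")
def ideal_solvent():
    return ideal_gas_solvent(density=0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
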