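"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from hydrafibre.synth import (gen_ideal_gas, gen_lattice, gen_micelle,
                              gen_pa_bundle, gen_solvation_shell)


@pytest.fixture(scope="session")
def bundle():
    """Default paper-scale bundle: 6 fibres x 50 PAs, 50 Å spacing."""
    return gen_pa_bundle(seed=0)


@pytest.fixture(scope="session")
def micelle():
    return gen_micelle(seed=0)


@pytest.fixture(scope="session")
def shell_fixture():
    """Default solvation-shell fixture (first shell 2.85 Å, second 5.0 Å)."""
    return gen_solvation_shell()


@pytest.fixture(scope="session")
def ideal_gas_traj():
    return gen_ideal_gas(1000, [30.0, 30.0, 30.0], n_frames=20, seed=11)


@pytest.fixture(scope="session")
def fcc():
    return gen_lattice("fcc", 4.0, (4, 4, 4))


@pytest.fixture(scope="session")
def diamond_ice():
    return gen_lattice("diamond_ice", 6.0, (3, 3, 3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
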