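"""Shared fixtures: model systems and cached expensive computations."""

import numpy as np
import pytest

from overtone_sim.fixtures import load_fixture
from overtone_sim.floquet import interaction_terms


@pytest.fixture(scope="session")
def glycine():
    return load_fixture("glycine")


@pytest.fixture(scope="session")
def nav():
    return load_fixture("NAV")


@pytest.fixture(scope="session")
def glycine_terms(glycine):
    return interaction_terms(glycine.system)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def glycine_carrier_1984(glycine):
    """Carrier offset on the +2 sideband, glycine at 19.84 kHz MAS.

    Resolved once per session by the two-pass peak pick at coarse grid;
    shared by the acceptance-level tests that run at these conditions.
    """
    from overtone_sim.sequences import SimSettings, resolve_carrier
    settings = SimSettings(mas_hz=19.84e3, rank=5, grid_order=17,
                           lb_hz=300.0, n_phase=32, n_alpha=12)
    return resolve_carrier(glycine.system, settings)
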