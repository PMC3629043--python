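"""Shared fixtures: absorber bases, training fixtures, photon records, and
the small three-absorber toy problem used for exhaustive-search checks."""

from __future__ import annotations

import warnings

import pytest

import waveopt as w
from waveopt.synthetic_data import ToyUnmixingProblem

warnings.filterwarnings("ignore", message=".*diffusion approximation.*")


@pytest.fixture(scope="session")
def basis():
    return w.surrogate_basis()


@pytest.fixture(scope="session")
def table1_params():
    return w.table1_fixture()


@pytest.fixture(scope="session")
def grid10():
    return w.WavelengthGrid(450, 600, 10)


@pytest.fixture(scope="session")
def photon_records():
    return w.simulate_photon_records(baseline_mus=10.0, n_photons=400_000,
                                     seed=5)


@pytest.fixture(scope="session")
def toy_problem():
    return ToyUnmixingProblem()
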