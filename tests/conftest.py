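"""Shared fixtures: packaged tables and reference values used across suites."""

from __future__ import annotations

import numpy as np
import pytest

from greenextract import datasets
from greenextract.hsp import HansenParameters


@pytest.fixture(scope="session")
def solvents():
    return datasets.load_solvents()


@pytest.fixture(scope="session")
def sphere_fit_solvents():
    return datasets.load_solvents("sphere_fit")


@pytest.fixture(scope="session")
def sphere_fit_hansen(sphere_fit_solvents):
    return {name: rec.hansen for name, rec in sphere_fit_solvents.items()}


@pytest.fixture(scope="session")
def red_panel():
    return datasets.load_red_panel()


@pytest.fixture(scope="session")
def hexane(solvents):
    return solvents["n-hexane"]


@pytest.fixture(scope="session")
def methf(solvents):
    return solvents["MeTHF"]


@pytest.fixture(scope="session")
def kinetics_defaults():
    return datasets.load_kinetics_defaults()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_hansen(rng, low=10.0, high=22.0) -> HansenParameters:
    d, p, h = rng.uniform(low, high), rng.uniform(0, 12), rng.uniform(0, 20)
    return HansenParameters(d, p, h)
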