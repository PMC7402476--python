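"""Shared fixtures: the case-study model, its enumeration, and the
hand-verified structure table it must reproduce."""

from __future__ import annotations

import warnings

import pytest

from ecopgraph import (
    ModelWarning,
    brute_force,
    case_study_model,
    enumerate_structures,
    random_model,
)

# The 20 viable structures of the case-study ecosystem, as unit sets.
# Frozen from the published structure table of the stylized system; the
# occurrence counts per unit are (Plant1 12, Plant2 16, Plant3 12,
# Herbivore1 20, Herbivore2 10, Carnivore 10, Soil_microbes 20).
_ABBREV = {
    "P1": "Plant1",
    "P2": "Plant2",
    "P3": "Plant3",
    "H1": "Herbivore1",
    "H2": "Herbivore2",
    "C": "Carnivore",
    "SM": "Soil_microbes",
}
_ROWS = [
    "P1 P2 P3 H1 H2 C SM",
    "P1 P2 P3 H1 H2 SM",
    "P1 P2 P3 H1 C SM",
    "P1 P2 P3 H1 SM",
    "P1 P3 H1 C SM",
    "P1 P3 H1 SM",
    "P1 P3 H1 H2 C SM",
    "P1 P3 H1 H2 SM",
    "P1 P2 H1 H2 C SM",
    "P1 P2 H1 H2 SM",
    "P1 P2 H1 C SM",
    "P1 P2 H1 SM",
    "P2 P3 H1 H2 C SM",
    "P2 P3 H1 H2 SM",
    "P2 P3 H1 C SM",
    "P2 P3 H1 SM",
    "P2 H1 H2 C SM",
    "P2 H1 H2 SM",
    "P2 H1 C SM",
    "P2 H1 SM",
]

EXPECTED_STRUCTURES = frozenset(
    frozenset(_ABBREV[tok] for tok in row.split()) for row in _ROWS
)
EXPECTED_N_I = {
    "Plant1": 12,
    "Plant2": 16,
    "Plant3": 12,
    "Herbivore1": 20,
    "Herbivore2": 10,
    "Carnivore": 10,
    "Soil_microbes": 20,
}


@pytest.fixture(scope="session")
def case_model():
    return case_study_model()


@pytest.fixture(scope="session")
def case_result(case_model):
    return enumerate_structures(case_model)


@pytest.fixture(scope="session")
def case_brute(case_model):
    return brute_force(case_model)


@pytest.fixture(scope="session")
def expected_structures():
    return EXPECTED_STRUCTURES


@pytest.fixture(scope="session")
def expected_n_i():
    return EXPECTED_N_I


def quiet_random_model(*args, **kwargs):
    """random_model with modelling warnings silenced (they are expected)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelWarning)
        return random_model(*args, **kwargs)


@pytest.fixture()
def make_random_model():
    return quiet_random_model
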