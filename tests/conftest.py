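"""Shared fixtures: small deterministic synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from stepps.grids import KernelParams, build_grid, weight_matrix
from stepps.synthetic import (
    PRESETS,
    simulate_age_draws,
    simulate_composition,
    simulate_records,
)


@pytest.fixture(scope="session")
def tiny_truth():
    return simulate_composition(PRESETS["tiny"], np.random.default_rng(123))


@pytest.fixture(scope="session")
def tiny_records(tiny_truth):
    return simulate_records(tiny_truth, np.random.default_rng(124))


@pytest.fixture(scope="session")
def tiny_ages(tiny_records):
    return simulate_age_draws(tiny_records, n_draws=3, rng=np.random.default_rng(125))


@pytest.fixture(scope="session")
def grid3x3():
    return build_grid((72.0, 72.0), 24.0)


@pytest.fixture(scope="session")
def weights3x3(grid3x3):
    return weight_matrix(grid3x3, KernelParams("inverse_power_law", a=24.0, b=4.0))
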