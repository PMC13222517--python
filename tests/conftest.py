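"""Shared fixtures.

The expensive fixture is ``trained_runs``: five independent simulation +
training runs at the desk-scale schedule (stages 100/100/200), shared
session-wide by the acceptance tests and the integration checks so each
model is trained exactly once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from usadae import (
    DESimConfig,
    USADAEConfig,
    fit_usadae,
    simulate_de_dataset,
)

warnings.filterwarnings("ignore", message=".*outside the recommended range.*")

#: desk-scale training schedule: full stages 1-2, stage 3 shortened to 200
DESK_EPOCHS = (100, 100, 200)
N_RUNS = 5


@pytest.fixture(scope="session")
def trained_runs():
    """[(dataset, fitted_pipeline), ...] for seeds 1..5, default simulation."""
    runs = []
    for seed in range(1, N_RUNS + 1):
        ds = simulate_de_dataset(seed=seed)
        fitted = fit_usadae(
            ds.observed_expression,
            ds.group,
            USADAEConfig(seed=seed, epochs=DESK_EPOCHS),
        )
        runs.append((ds, fitted))
    return runs


@pytest.fixture(scope="session")
def trained_run(trained_runs):
    """First of the shared runs, for single-model checks."""
    return trained_runs[0]


@pytest.fixture()
def small_de_dataset():
    """A fast small-scale dataset for unit-level checks."""
    return simulate_de_dataset(
        DESimConfig(n_genes=200, n_cases=40, n_controls=40, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
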