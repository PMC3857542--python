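"""Shared fixtures: generating parameters, a reference synthetic dataset at
the typical experimental scale (720 go / 480 stop trials over five fixed
delays), and a converged posterior fit reused by the diagnostics, output and
model-check tests."""

import numpy as np
import pytest

from stoprace import (
    DesignSpec,
    ExGaussParams,
    MCMCSettings,
    RaceParams,
    dataset_from_frame,
    map_start,
    run_chains,
    simulate_participant,
)

TRUE_PARAMS = RaceParams(
    go=ExGaussParams(500.0, 50.0, 100.0),
    stop=ExGaussParams(200.0, 20.0, 50.0),
)

FIXED_DESIGN = DesignSpec(
    n_go=720,
    ssds={200.0: 96, 250.0: 96, 300.0: 96, 350.0: 96, 400.0: 96},
)


@pytest.fixture(scope="session")
def true_params():
    return TRUE_PARAMS


@pytest.fixture(scope="session")
def fixed_design():
    return FIXED_DESIGN


@pytest.fixture(scope="session")
def sim_dataset():
    """One participant at the reference design, fixed seed."""
    rng = np.random.default_rng(20240501)
    frame = simulate_participant(TRUE_PARAMS, FIXED_DESIGN, rng)
    return dataset_from_frame(frame)


@pytest.fixture(scope="session")
def fitted_chains(sim_dataset):
    """A converged three-chain fit of the reference dataset."""
    settings = MCMCSettings(
        n_chains=3, n_samples=3000, burn_in=1000, thin=2, seed=11
    )
    start = map_start(sim_dataset.arrays(), seed=11)
    return run_chains(sim_dataset, settings=settings, start=start)
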