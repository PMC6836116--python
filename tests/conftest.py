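import numpy as np
import pytest

from latmask import PopulationParams, SessionDesign, simulate_dataset


@pytest.fixture(scope="session")
def baseline_design():
    """Paper-default contrast levels/reps, baseline block only."""
    return SessionDesign(flanker_distances=())


@pytest.fixture(scope="session")
def small_design():
    """Reduced factorial for fast end-to-end tests."""
    return SessionDesign(
        contrast_levels=(0.01, 0.03, 0.06, 0.09),
        reps_per_level=15,
        flanker_distances=(1, 4, 12),
    )


@pytest.fixture(scope="session")
def zero_sigma_pop():
    return PopulationParams(
        beta=(-0.5, 29.0, 0.0, 0.0),
        sigma_re=((0.0, 0.0), (0.0, 0.0)),
        group_sizes=(25, 25),
    )


@pytest.fixture(scope="session")
def hetero_pop():
    return PopulationParams(
        beta=(-0.5, 29.0, -0.4, 12.0),
        sigma_re=((0.04, 0.0), (0.0, 16.0)),
        group_sizes=(31, 24),
    )


@pytest.fixture(scope="session")
def baseline_table(hetero_pop, baseline_design):
    return simulate_dataset(hetero_pop, baseline_design, seed=101)


@pytest.fixture(scope="session")
def zero_sigma_table(zero_sigma_pop, baseline_design):
    return simulate_dataset(zero_sigma_pop, baseline_design, seed=202)
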