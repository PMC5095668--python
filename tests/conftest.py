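"""Shared fixtures: reference trajectories are expensive, so compute once."""

import warnings

import pytest
from hypothesis import settings

from mitoswitch import kinetics

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

HOUR = 3600.0


def _reference_trajectory(variant: str, horizon_h: float, grid: float = 10.0):
    params = kinetics.reference_parameters(variant)
    model = kinetics.build_model(params)
    init = kinetics.reference_initial_state(params.pore_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return kinetics.simulate(model, init, horizon=horizon_h * HOUR, grid=grid)


@pytest.fixture(scope="session")
def model_i_trajectory():
    """Tetramer-pore model, bundled reference parameters, 30 h."""
    return _reference_trajectory("I", 30.0)


@pytest.fixture(scope="session")
def model_ii_trajectory():
    """256-mer-pore model, bundled reference parameters, 50 h."""
    return _reference_trajectory("II", 50.0)


@pytest.fixture(scope="session")
def default_pop():
    from mitoswitch import synthetic

    return synthetic.default_population()
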