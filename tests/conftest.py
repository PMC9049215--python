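"""Shared fixtures: model parameters and converged periodic gaits.

The expensive objects (Newton-converged cycles, the acceptance sweep)
are session-scoped so every test file shares one computation.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from spinegait import ModelParameters, SolverSettings
from spinegait.search import continuation_sweep, newton_solve

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def settings() -> SolverSettings:
    return SolverSettings()


@pytest.fixture(scope="session")
def branch1_solution(params, settings):
    """Converged spine-extending gait at (y*=0.69, thetadot*=-1.5,
    E=4500 J); the seed is a coarse unconverged guess."""
    return newton_solve([0.49, 0.57, 0.53], (0.69, -1.5, 4500.0),
                        params, settings)


@pytest.fixture(scope="session")
def branch2_solution(params, settings):
    """Converged spine-opposing gait at the same section target."""
    return newton_solve([-0.27, 0.57, 0.61], (0.69, -1.5, 4500.0),
                        params, settings)


@pytest.fixture(scope="session")
def acceptance_sweep(params, settings):
    """Periodic-gait sweep at E = 4500 J over all four apex pitch rates,
    with Floquet stability; shared by the acceptance tests."""
    sweep = continuation_sweep(
        4500.0, [-1.5, -0.5, 0.5, 1.5], (0.60, 0.78), p=params,
        settings=settings, y_step=0.01, with_floquet=True)
    assert sweep.solutions, "sweep found no periodic solutions"
    return sweep


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
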