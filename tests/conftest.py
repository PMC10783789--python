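"""Shared fixtures: synthetic sessions at the sizes used throughout the suite.

Heavy fixtures are session-scoped so the default study-size session (200
neurons, 12,000 frames per context) and the reduced manifold-stage cohorts
are generated once per run.
"""

import numpy as np
import pytest

from copingmanifold.config import AnalysisConfig
from copingmanifold.synthetic import (GeneratorParams, generate_cohort,
                                      generate_multiday, generate_session)


@pytest.fixture(scope="session")
def default_session():
    """Study-size single session (200 neurons, 12,000 TS frames), seed 1."""
    params = GeneratorParams()
    session, truth = generate_session(params, 1, None, np.random.default_rng(1))
    return session, truth, params


@pytest.fixture(scope="session")
def small_session():
    """Small, fast session for structural unit tests."""
    params = GeneratorParams(n_neurons=60, n_frames_baseline=1200, n_frames_ts=1600)
    session, truth = generate_session(params, 1, None, np.random.default_rng(3))
    return session, truth, params


@pytest.fixture(scope="session")
def manifold_params():
    """Reduced problem size for embedding/alignment runs."""
    return GeneratorParams(n_neurons=150, n_frames_baseline=2000, n_frames_ts=3000)


@pytest.fixture(scope="session")
def manifold_config():
    return AnalysisConfig(isomap_neighbors=100)


@pytest.fixture(scope="session")
def multiday_bundle(manifold_params):
    """Three-day recording of one animal with partial cell overlap."""
    sessions, regmap, truth = generate_multiday(
        manifold_params, [1, 3, 9], np.random.default_rng(11))
    return sessions, regmap, truth


@pytest.fixture(scope="session")
def cohort_bundle(manifold_params):
    """Two animals sharing one latent law under different neuron loadings."""
    return generate_cohort(manifold_params, 2, np.random.default_rng(21), days=[1, 3])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
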