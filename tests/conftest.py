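"""Shared fixtures: synthetic movies at two scales plus their pipeline runs.

The *small* movie (6 founders, one division round) keeps unit tests fast;
the *default* movie uses the generator's default study conditions
(12 founders, two division rounds, 128->512-cell-like cycle elongation)
and backs the end-to-end accuracy checks.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from blastula import (SimConfig, simulate_truth, render_movie,
                      run_pipeline, PipelineConfig)


SMALL_KW = dict(
    n_founders=6, n_generations=1, field_shape=(16, 144, 144),
    cycle_mean_min=(10.0, 13.0), cycle_sd_min=(0.8, 1.0),
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=5, **SMALL_KW)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_movie(small_config, small_truth):
    return render_movie(small_truth, small_config)


@pytest.fixture(scope="session")
def small_result(small_movie):
    return run_pipeline(small_movie, PipelineConfig())


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return simulate_truth(default_config)


@pytest.fixture(scope="session")
def default_movie(default_config, default_truth):
    return render_movie(default_truth, default_config)


@pytest.fixture(scope="session")
def default_result(default_movie):
    return run_pipeline(default_movie, PipelineConfig())


@pytest.fixture(scope="session")
def noisefree_config():
    from blastula import NoiseParams
    return SimConfig(seed=7, noise=NoiseParams(background=100.0,
                                               gaussian_sd=0.0,
                                               photon_scale=0.0),
                     **SMALL_KW)


@pytest.fixture(scope="session")
def noisefree_truth(noisefree_config):
    return simulate_truth(noisefree_config)


@pytest.fixture(scope="session")
def noisefree_movie(noisefree_config, noisefree_truth):
    return render_movie(noisefree_truth, noisefree_config)


@pytest.fixture(scope="session")
def noisefree_result(noisefree_movie):
    return run_pipeline(noisefree_movie, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
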