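import logging

import pytest

from poletrack import (AnalysisParams, SimConfig, analyze_movie,
                       render_movie, simulate_population)

logging.getLogger("poletrack").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_cells=6, seed=7)


@pytest.fixture(scope="session")
def small_movie(small_config):
    """A six-founder movie with ground truth, rendered once per session."""
    truths = simulate_population(small_config)
    stack, truth = render_movie(truths, small_config)
    return small_config, truths, stack, truth


@pytest.fixture(scope="session")
def small_movie_result(small_movie):
    _cfg, _truths, stack, _truth = small_movie
    return analyze_movie(stack, AnalysisParams())
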