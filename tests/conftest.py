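"""Shared fixtures: one default synthetic transect and one pipeline run.

Session-scoped so the expensive generation and end-to-end run happen once.
"""

import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from coccoprod.pipeline import RunConfig, run_pipeline
from coccoprod.synthetic import GeneratorConfig, generate_transect

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def transect():
    """Default-config synthetic transect: (metadata, env, census, coccoliths, truth)."""
    return generate_transect(GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline run on the default simulated transect."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_pipeline(RunConfig(seed=DEFAULT_SEED))
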