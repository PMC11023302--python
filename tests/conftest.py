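import numpy as np
import pytest

from nestmotion import RunConfig, run_pipeline, small_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pipeline_semi():
    """Shared end-to-end run: scaled-down episode, semicircular suppression."""
    return run_pipeline(RunConfig(scenario=small_scenario(seed=1)))


@pytest.fixture(scope="session")
def pipeline_linear():
    """Shared end-to-end run with linear-ramp shimmer suppression."""
    return run_pipeline(
        RunConfig(scenario=small_scenario(seed=1, inhibition_model="linear_ramp"))
    )
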