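import numpy as np
import pytest

from esa import agent
from esa.pipeline import PipelineConfig, segment_and_cluster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def agent_recording():
    """A medium-length discrete-state agent recording (session-cached)."""
    return agent.simulate(agent.default_config(seed=1), 6000)


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline config with a test-sized number of EM restarts."""
    return PipelineConfig(k_range=(1, 2, 3, 4), n_restarts=10, seed=11)


@pytest.fixture(scope="session")
def agent_result(agent_recording, fast_config):
    """Full segment+cluster result on the agent recording (session-cached)."""
    return segment_and_cluster(agent_recording.ects, fast_config)


@pytest.fixture(scope="session")
def separated_curves():
    """Three well-separated synthetic curve clusters with known labels."""
    return agent.make_spline_cluster_curves(
        K=3, n_per_cluster=60, separation=0.5, noise_sd=0.05, seed=7
    )
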