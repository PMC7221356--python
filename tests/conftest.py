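import numpy as np
import pytest

from arenatrack import ArenaSimConfig, PipelineConfig, simulate_session, track_session


@pytest.fixture(scope="session")
def default_sim():
    """One rendered default-condition session with its ground truth."""
    cfg = ArenaSimConfig(n_frames=200, seed=11)
    frames, truth = simulate_session(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def default_track(default_sim):
    """The default session tracked with the default pipeline config."""
    _, frames, truth = default_sim
    log = track_session(frames, PipelineConfig())
    return log, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
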