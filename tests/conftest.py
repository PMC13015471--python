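import numpy as np
import pytest

from stimnet import synthdata as sd
from stimnet.tracto import chaco_profile


@pytest.fixture(scope="session")
def config():
    return sd.SynthConfig(seed=1)


@pytest.fixture(scope="session")
def atlas(config):
    return sd.generate_atlas(config.n_parcels, config.seed)


@pytest.fixture(scope="session")
def tractogram(atlas, config):
    return sd.generate_tractogram(atlas, config)


@pytest.fixture(scope="session")
def encoding_weights(atlas, config):
    return sd.generate_encoding_network(atlas, 12, config.seed)


@pytest.fixture(scope="session")
def cohort(atlas, tractogram, encoding_weights, config):
    return sd.generate_cohort(atlas, tractogram, encoding_weights, config)


@pytest.fixture(scope="session")
def cumulative_closed(atlas, tractogram, cohort):
    """Cumulative ChaCo matrix (sites x parcels) for the closed-loop sites."""
    sites, _ = cohort
    closed = [s for s in sites if s.mode == "closed"]
    return np.array([chaco_profile(tractogram, s, atlas).cumulative for s in closed])
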