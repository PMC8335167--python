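import numpy as np
import pytest
from hypothesis import settings

from genewise import SimulationConfig, generate_study

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """Default synthetic study: 50 genes x 20 SNPs, 5 planted risk genes."""
    out = tmp_path_factory.mktemp("study_default")
    cfg = SimulationConfig(seed=20)
    return cfg, generate_study(cfg, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
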