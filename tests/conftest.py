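import numpy as np
import pytest

from synid.pipeline import PipelineConfig, run_synthetic_study
from synid.synthetic_data import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """Small seeded synthetic session shared across decoder-level tests."""
    cfg = GeneratorConfig(seed=7, n_train_per_direction=6, n_test_per_direction=4)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_study(small_session):
    """Full train->decode->evaluate run on the small session."""
    return run_synthetic_study(small_session, PipelineConfig())


@pytest.fixture(scope="session")
def trained_model(small_study):
    return small_study["model"]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
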