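import numpy as np
import pytest

from ncrtfusion import default_config, generate_cohort
from ncrtfusion.evaluation import ModelConfig
from ncrtfusion.fusion import FusionConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=149, planted signal), fixed seed."""
    return generate_cohort(default_config(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast pipeline tests."""
    cfg = default_config()
    cfg.n_patients = 36
    return generate_cohort(cfg, seed=5)


@pytest.fixture()
def fast_model_config():
    """Few-epoch model settings for pipeline mechanics (not accuracy) tests."""
    return ModelConfig(fusion=FusionConfig(epochs=25))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
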