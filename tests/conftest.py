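import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_config():
    from arrlogic import SimConfig
    return SimConfig(n_background_genes=300, genes_per_structure=6, seed=42)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """Small planted study shared by the model/pipeline tests."""
    from arrlogic import generate_expression_study
    return generate_expression_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_results(tiny_study):
    from arrlogic import KnockoutLogicModel
    study, truth = tiny_study
    res = KnockoutLogicModel(study).fit(seed=7)
    return res, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
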