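import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-gene error-free panel shared by the integration tests."""
    from homoeoseq.simulate import SimulationParams, simulate_variety_panel

    params = SimulationParams(
        n_genes=20, depth=10.0, base_error_rate=0.0, bias_fraction=0.0, seed=1
    )
    return simulate_variety_panel(params)


@pytest.fixture(scope="session")
def small_callsets(small_dataset):
    from homoeoseq import pipeline

    return pipeline.call_all_varieties(small_dataset)


@pytest.fixture(scope="session")
def small_classified(small_dataset, small_callsets):
    from homoeoseq import pipeline

    return pipeline.classify_panel(small_dataset, small_callsets)


@pytest.fixture(scope="session")
def small_phase(small_dataset, small_callsets, small_classified):
    from homoeoseq import pipeline

    return pipeline.phase_panel(small_dataset, small_callsets, small_classified)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
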