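import pytest

from mirchromnet.config import PipelineConfig
from mirchromnet.pipeline import analyze_bundle
from mirchromnet.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def pconfig() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic bundle (partial reproducibility + noise)."""
    return simulate_bundle(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def result(bundle):
    return analyze_bundle(bundle)


@pytest.fixture(scope="session")
def clean_bundle():
    """Fully reproducible, noise-free bundle for exact-recovery checks."""
    return simulate_bundle(
        SimulationConfig(seed=5, edge_reproducibility=1.0, noise_edge_rate=0.0)
    )


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    return analyze_bundle(clean_bundle)
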