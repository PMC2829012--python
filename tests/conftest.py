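import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sagebias import ProtocolConfig, TagLibrary, run_coverage_experiment

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy3_library() -> TagLibrary:
    """Three-gene library with non-uniform tag-formation probabilities."""
    return TagLibrary(["gA", "gB", "gC"], np.array([5, 2, 0]), np.array([0.9, 0.5, 0.7]))


@pytest.fixture(scope="session")
def protocol_coverage():
    """Coverage study at protocol settings: 1,000 genes in the published
    per-bin counts, p = 0.55, 15,000 tags/library, 200 replicate libraries,
    full-length chains. Shared session-wide because it is by far the most
    expensive computation in the suite."""
    config = ProtocolConfig(
        n_libraries=200,
        seed=20100203,
        combinations=(("dpb", "flat"), ("dpb", "tub"), ("dmb", "flat")),
    )
    return run_coverage_experiment(config)
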