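import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220725)


@pytest.fixture
def published():
    """The packaged fixture of published per-SNP and pooled estimates."""
    from mrkit.reproduce import load_published_estimates

    return load_published_estimates()
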