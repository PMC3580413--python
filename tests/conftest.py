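import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small in-memory cohort from the 'tiny' preset (shared, read-only)."""
    from gxescreen.simulate import generate_dataset

    return generate_dataset("tiny", seed=11)


@pytest.fixture(scope="session")
def f13_dataset():
    """The planted-interaction preset at its default size (shared)."""
    from gxescreen.simulate import generate_dataset

    return generate_dataset("f13a1_like", seed=5)
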