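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


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free 10-cell scene; shared by segmentation/quantification tests."""
    from magicquant import ImagingParams, generate_scene

    return generate_scene(
        ImagingParams(image_shape=(12, 200, 200), cell_count=10, noise_sd=0.0, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
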