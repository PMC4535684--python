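import numpy as np
import pytest

from dafish.synthetic import SceneSpec


@pytest.fixture
def noise_free_scene() -> SceneSpec:
    """Symmetric, noise-free default scene (two equal Gaussian spots)."""
    return SceneSpec(noise_model="none")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
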