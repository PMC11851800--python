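import numpy as np
import pytest

from idcc.synthetic import SynthProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_profile():
    """Noise-free, well-separated cells: every stage should recover exactly."""
    return SynthProfile(
        name="clean",
        width=256,
        height=256,
        count_mean=12,
        count_sd=4,
        radius_range=(3, 6),
        noise_sd=0,
        illumination_amplitude=0,
        min_separation=14,  # >= 2 * max radius + 2
        seed=7,
    )
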