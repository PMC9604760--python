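import numpy as np
import pytest

from bcl6quant.synthetic import SlideSpec, generate_slide


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


@pytest.fixture(scope="session")
def default_slide():
    """One synthetic slide at the default spec, shared across tests."""
    return generate_slide(SlideSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_slide():
    """A slide without read noise and with tight staining distributions,
    for exact ground-truth threshold-coverage checks."""
    from bcl6quant.synthetic import IntensitySpec

    return generate_slide(
        SlideSpec(
            noise_sigma=0.0,
            epithelial_intensity=IntensitySpec("gaussian", 130, 8),
            stromal_intensity=IntensitySpec("gaussian", 110, 8),
            seed=11,
        )
    )
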