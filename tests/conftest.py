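import numpy as np
import pytest

from toccsl.synthetic import CameraModel, GroundTruth, MonomerBrightnessLaw


@pytest.fixture
def law():
    return MonomerBrightnessLaw(median=100.0, geometric_sd=1.4)


@pytest.fixture
def degenerate_law():
    """Zero-variance law concentrated at 100 photons."""
    return MonomerBrightnessLaw(median=100.0, geometric_sd=1.0)


@pytest.fixture
def camera():
    return CameraModel(offset=100.0, inverse_gain=4.0, read_noise_sd=1.5,
                       pixel_size=0.16)


@pytest.fixture
def fine_camera():
    """Low-quantization, noise-free camera for forward-render oracles."""
    return CameraModel(offset=100.0, inverse_gain=0.1, read_noise_sd=0.0,
                       pixel_size=0.16)


@pytest.fixture
def wildtype_truth(law):
    return GroundTruth(fractions=(0.6, 0.4), monomer_law=law, density=0.2,
                       seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
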