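import numpy as np
import pytest

from lgequant import NoiseModel, PhantomSpec
from lgequant.synthetic import simulate_image


@pytest.fixture
def model_k8():
    """The study's noise model: background SD 2.05, 8 phased-array coils."""
    return NoiseModel(sigma=2.05, coils=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def big_phantom():
    """A noise-only phantom with >= 1e4 pixels in both the annulus and the
    background ROI (used by recovery and self-consistency checks)."""
    spec = PhantomSpec(
        image_shape=(400, 400),
        pixel_spacing_mm=(1.0, 1.0),
        endo_radius_mm=25.0,
        epi_radius_mm=65.0,
        background_roi_side_mm=100.0,
        seed=7,
    )
    img, seg, truth = simulate_image(spec)
    return spec, img, seg, truth


def sos_magnitude(rng, sigma_channel, coils, n, amplitude=0.0):
    """Independent oracle generator: root-sum-of-squares of K complex
    Gaussian channels, written out longhand (no scipy.stats.chi)."""
    per = amplitude / np.sqrt(coils)
    re = rng.normal(per, sigma_channel, size=(coils, n))
    im = rng.normal(0.0, sigma_channel, size=(coils, n))
    return np.sqrt((re**2 + im**2).sum(axis=0))
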