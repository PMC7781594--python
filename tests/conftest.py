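import numpy as np
import pytest

from sarcoquant.synthetic import gen_em_micrograph


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free straight-Z-disk scene shared by segmentation tests."""
    img, gt = gen_em_micrograph(
        sl_um=3.3,
        n_sarcomeres=3,
        nm_per_px=8.0,
        height_px=200,
        waviness_amplitude_nm=0.0,
        noise_fraction=0.0,
        seed=0,
    )
    return img, gt


@pytest.fixture(scope="session")
def noisy_scene():
    img, gt = gen_em_micrograph(
        sl_um=3.3,
        n_sarcomeres=3,
        nm_per_px=8.0,
        height_px=200,
        waviness_amplitude_nm=0.0,
        noise_fraction=0.03,
        seed=1,
    )
    return img, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
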