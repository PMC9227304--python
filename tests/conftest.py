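import numpy as np
import pytest

import ramancaps as rc


@pytest.fixture(scope="session")
def axis():
    return rc.default_axis()


@pytest.fixture(scope="session")
def clean_spectrum(axis):
    """One synthetic spectrum with no stochastic jitter or noise."""
    profile = rc.synthetic.class_profile(
        0, amplitude_cv=0.0, intensity_cv=0.0, noise_sigma=0.0
    )
    return rc.generate_spectrum(profile, axis, seed=0, sample_id="clean", variety="LJ47")


@pytest.fixture(scope="session")
def noisy_spectrum(axis):
    profile = rc.synthetic.class_profile(2)
    return rc.generate_spectrum(profile, axis, seed=5, sample_id="noisy", variety="SJ13")


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Narrow capsule net: same 28 -> 20 -> 6 topology, few channels."""
    from ramancaps.capsnet import CapsNetConfig

    return CapsNetConfig(conv1_channels=3, primary_channels=8, class_caps_dim=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
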