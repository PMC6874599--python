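import numpy as np
import pytest

from strainnet import ProfileGenParams, VelocityProfile, generate_profiles


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_profiles():
    """A pool of 1000 random impact-like profiles for property checks."""
    return generate_profiles(ProfileGenParams(n_impacts=1000, seed=7))


@pytest.fixture
def pulse_profile():
    """A clean single pulse along a fixed oblique direction, peak 10 rad/s."""
    t = np.arange(0.0, 41.0)
    scalar = 10.0 * np.sin(np.pi * t / 40.0) ** 2
    u = np.array([0.6, 0.64, 0.48])  # unit vector
    return VelocityProfile("pulse", 1.0, u[:, None] * scalar[None, :])
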