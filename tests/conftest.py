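import numpy as np
import pytest

from usenhance import GrayImage, NoiseSpec, PhantomSpec, add_impulse_noise, make_phantom


@pytest.fixture
def random_image():
    """Factory for seeded uniform-random 8-bit images."""

    def _make(seed: int, shape=(32, 32)) -> GrayImage:
        rng = np.random.default_rng(seed)
        return GrayImage(rng.integers(0, 256, shape, dtype=np.int64))

    return _make


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom rendered once per session: (clean, structure_mask)."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noisy_phantom(default_phantom):
    """Default phantom with 10% salt-and-pepper: (clean, noisy, corrupted_mask)."""
    clean, _ = default_phantom
    noisy, corrupted = add_impulse_noise(clean, NoiseSpec(density=0.10, seed=11))
    return clean, noisy, corrupted
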