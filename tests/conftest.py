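import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile("deterministic", derandomize=True)
hypothesis.settings.load_profile("deterministic")

from wspdeposit import BinnedSpreadFactor, ConstantSpreadFactor


@pytest.fixture
def constant_model():
    return ConstantSpreadFactor().fit()


@pytest.fixture
def binned_model():
    return BinnedSpreadFactor().fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def rasterize_oracle(width, height, center, radius_px):
    """Brute-force pixel-center-in-circle test, independent of the package."""
    cx, cy = center
    pixels = set()
    for y in range(height):
        for x in range(width):
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius_px**2:
                pixels.add((x, y))
    return pixels
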