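import numpy as np
import pytest

from braintex import GreyImage, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A small random 4-level image for exact pair-counting checks."""
    return GreyImage(rng.integers(0, 4, size=(9, 11)), levels=4)


@pytest.fixture
def spec64():
    """Synthetic generator spec scaled to 64x64 test images."""
    return SyntheticSpec.for_size(64)


@pytest.fixture
def spec64_noise_free():
    return SyntheticSpec.for_size(64, noise_sigma=0.0)


def brute_force_glcm(pixels: np.ndarray, levels: int, dr: int, dc: int, symmetric: bool):
    """Exhaustive per-pair co-occurrence enumeration (independent oracle)."""
    H, W = pixels.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[pixels[r, c], pixels[r2, c2]] += 1
                if symmetric:
                    counts[pixels[r2, c2], pixels[r, c]] += 1
    return counts
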