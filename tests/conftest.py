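import numpy as np
import pytest

from organoid_morph import PhantomSpec, SegmentationParams, generate_phantom


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def disk_phantom():
    """Noisy blurred dark disk (radius 60 px) on a bright field."""
    spec = PhantomSpec(radius_px=60, image_size_px=164, seed=1)
    return generate_phantom(spec)


def disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    """Centered discrete disk mask with a clear border margin."""
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = n / 2 - 0.5
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def square_mask(side: int, pad: int = 20) -> np.ndarray:
    n = side + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m
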