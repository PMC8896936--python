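import numpy as np
import pytest

from ribseg.geometry import BinaryMask, VolumeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0), p=0.2,
                nonempty=True) -> BinaryMask:
    """Random binary mask; re-draws until nonempty when requested."""
    geometry = VolumeGeometry(size=shape, spacing_mm=spacing)
    while True:
        values = (rng.uniform(size=shape) < p).astype(np.uint8)
        if values.any() or not nonempty:
            return BinaryMask(values=values, geometry=geometry)


@pytest.fixture
def mask_pair_factory(rng):
    def factory(shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0), p=0.2):
        return random_mask(rng, shape, spacing, p), random_mask(rng, shape, spacing, p)
    return factory
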