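import numpy as np
import pytest

from radpipe.volume import CaseVolume


def strip_volume(values, axis=0):
    """A 1-D strip of intensities embedded in a 3-D volume."""
    values = np.asarray(values, dtype=float)
    shape = [1, 1, 1]
    shape[axis] = len(values)
    img = values.reshape(shape)
    return CaseVolume("strip", img, np.ones(shape, bool))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_volume(rng):
    """A noisy blob: random intensities in a random-ish mask, 3-D."""
    img = rng.normal(100, 15, size=(6, 6, 6))
    mask = np.zeros((6, 6, 6), bool)
    mask[1:5, 1:5, 1:5] = rng.random((4, 4, 4)) > 0.3
    mask[2, 2, 2] = True  # guarantee nonempty
    return CaseVolume("rand", img, mask)
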