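import numpy as np
import pytest

from mmdir.geometry import LabelMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.uniform(0.0, 100.0, (16, 16, 16)))


@pytest.fixture
def aniso_volume(rng):
    return Volume(
        rng.uniform(0.0, 100.0, (12, 10, 8)),
        spacing=(0.7, 1.1, 5.0),
        origin=(-10.0, 4.0, 2.5),
    )


@pytest.fixture
def cube_mask():
    data = np.zeros((16, 16, 16), bool)
    data[4:10, 4:10, 4:10] = True
    return LabelMask(data)


def identity_transform():
    class _Identity:
        bspline = None

        def apply(self, pts):
            return np.asarray(pts, dtype=float)

    return _Identity()


@pytest.fixture
def identity():
    return identity_transform()
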