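import numpy as np
import pytest

from hullprep import PointSet, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def square_plus_center():
    return make_fixture("square_plus_center")


def pointset(*pairs) -> PointSet:
    return PointSet.from_pairs(pairs)
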