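import numpy as np
import pytest

from histofield import RBFParams, make_point_image, point_field

CENTER = (250, 250)
SHAPE = (500, 500)


@pytest.fixture(scope="session")
def direct_params():
    return RBFParams.direct()


@pytest.fixture(scope="session")
def field_cache():
    """Memoized normalized direct fields for 500x500 point sets."""
    cache = {}

    def build(points, kernel_shape="separable", support="image"):
        key = (tuple(sorted(points)), kernel_shape, support)
        if key not in cache:
            if kernel_shape == "separable":
                params = RBFParams.direct()
            else:
                params = RBFParams.direct(kernel_shape=kernel_shape)
            cache[key] = point_field(points, SHAPE, params, support=support)
        return cache[key]

    return build


@pytest.fixture(scope="session")
def center_field(field_cache):
    return field_cache([CENTER])


def offset_points(distance):
    """A centre point plus one moved `distance` px along the row."""
    return [(CENTER[0], CENTER[1] + distance)]


@pytest.fixture(scope="session")
def pseudo_ihc():
    from histofield import make_pseudo_ihc

    return make_pseudo_ihc(512, 512, 20, 50, bone_bands=1, seed=7)
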