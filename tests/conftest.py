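import numpy as np
import pytest

from aneufsi.geometry import (MeshParams, build_case_r, make_box_fixture,
                              make_sphere_shell_fixture, make_tube_fixture)


@pytest.fixture(scope="session")
def case_model():
    return build_case_r()


@pytest.fixture(scope="session")
def coarse_tube():
    """Small graded tube used by flow tests (radius 2 mm, length 8 mm)."""
    bl = MeshParams(bl_growth=1.6, bl_first_layer=0.1, bl_total=0.3, core_size=0.7)
    return make_tube_fixture(2.0, 8.0, 0.7, bl=bl)


@pytest.fixture(scope="session")
def small_box():
    return make_box_fixture((10.0, 2.0, 2.0), (8, 3, 3),
                            side_tags={"x-": "fixed-plane", "x+": "interface"})


@pytest.fixture(scope="session")
def sphere_shell():
    return make_sphere_shell_fixture(10.0, 0.25, layers=2, subdiv=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
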