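import numpy as np
import pytest
from hypothesis import settings

import gutfloc as g

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def peg_1mda():
    return g.PolymerSpec("PEG 1 MDa", 1e6, 62.6)


@pytest.fixture(scope="session")
def peg_100kda():
    return g.PolymerSpec("PEG 100 kDa", 1e5, 16.7)


@pytest.fixture(scope="session")
def peg_3350():
    return g.PolymerSpec("PEG 3350", 3350.0, 2.9)


@pytest.fixture(scope="session")
def study_brush():
    """The grafted PEG 5 kDa layer on 1-µm polystyrene particles."""
    geom = g.brush_geometry(g.BrushDerivation(loading=4.6))
    return g.ColloidBrushSpec(
        core_radius=500.0,
        brush_length=geom.brush_length,
        brush_volume_fraction=geom.volume_fraction,
        chi=0.45,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
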