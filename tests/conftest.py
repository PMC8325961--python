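import numpy as np
import pytest

from afmstripes.gabor import GaborParams, build_bank
from afmstripes.imaging import HeightMap
from afmstripes.synthetic import MoleculeSpec, make_molecule_phantom


@pytest.fixture(scope="session")
def default_bank():
    return build_bank(GaborParams())


@pytest.fixture()
def straight_phantom():
    """Noiseless straight molecule: 100 nm backbone on a pixel row."""
    spec = MoleculeSpec(
        backbone_points=((60.0, 180.0), (160.0, 180.0)),
        stripe_width_nm=7.5,
        strand_height_nm=3.0,
    )
    return make_molecule_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_map(values, pixel_size_nm=1.5, **kw):
    return HeightMap(np.asarray(values, dtype=float), pixel_size_nm, **kw)
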