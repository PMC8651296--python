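import numpy as np
import pytest

from stimfret.structure import attach_effective_centers
from stimfret.synthetic import (
    default_site_pairs,
    make_planted_chain,
    make_synthetic_cad,
    synthetic_cad_transform,
)


@pytest.fixture(scope="session")
def cad_model():
    """Synthetic CAD dimer with effective dye centers on the label sites."""
    cad = make_synthetic_cad()
    _, cad_sites = default_site_pairs()
    sites = [(r, ch) for r in cad_sites for ch in ("A", "B")]
    return attach_effective_centers(cad, sites, seed=1)


@pytest.fixture(scope="session")
def cad_transform():
    return synthetic_cad_transform()


@pytest.fixture(scope="session")
def planted_chain(cad_model, cad_transform):
    return make_planted_chain(cad_model, cad_transform)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
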