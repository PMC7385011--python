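import numpy as np
import pytest

from clefscope.structures_io import Residue, Structure
from clefscope.synthetic import (SyntheticSpec, make_ensemble, make_family,
                                 make_multidomain_structure)


def bead_structure(coords, ids=None, aas=None, name="fixture", chain="A"):
    """Build a Structure from bare coordinates (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    ids = list(ids) if ids is not None else list(range(1, n + 1))
    aas = list(aas) if aas is not None else ["A"] * n
    return Structure([Residue(chain, ids[i], aas[i], tuple(coords[i]))
                      for i in range(n)], name=name)


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down enzyme architecture for fast unit tests."""
    return SyntheticSpec(n_gh9=60, n_linker=12, n_cbm=20, domain_radius=12.0,
                         n_frames=50, n_members=8, seed=0)


@pytest.fixture(scope="session")
def small_structure(small_spec):
    return make_multidomain_structure(small_spec)


@pytest.fixture(scope="session")
def small_family(small_spec, small_structure):
    s, ann = small_structure
    return make_family(s, ann, small_spec)


@pytest.fixture(scope="session")
def small_ensemble(small_spec, small_structure):
    s, ann = small_structure
    return make_ensemble(s, ann, small_spec)


@pytest.fixture(scope="session")
def small_modes(small_structure):
    from clefscope.enm import compute_modes

    s, _ = small_structure
    return compute_modes(s)


@pytest.fixture(scope="session")
def study_spec():
    """Full-scale study conditions (40-member family, 500-frame ensemble)."""
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def study_structure(study_spec):
    return make_multidomain_structure(study_spec)
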