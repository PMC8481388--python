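import numpy as np
import pytest

from ptmstruct import (HelixParams, PairParams, make_helix_pair,
                       make_ideal_helix, place_amide_hydrogens)
from ptmstruct.geometry import HelixAxis


@pytest.fixture(scope="session")
def helix20():
    """20-residue poly-Ala full-backbone helix with its exact axis."""
    return make_ideal_helix(HelixParams(n_res=20, backbone="FULL_BACKBONE"))


@pytest.fixture(scope="session")
def helix20_lys():
    """Full-backbone helix with a solvent-exposed lysine at residue 10."""
    seq = "A" * 9 + "K" + "A" * 10
    return make_ideal_helix(HelixParams(n_res=20, backbone="FULL_BACKBONE",
                                        sequence=seq))


@pytest.fixture(scope="session")
def corner_pair():
    """Crossing helical pair at plane distance 11.7 A, torsion -57 deg,
    with a lysine mid-way along the first helix."""
    return make_helix_pair(PairParams(plane_distance=11.7, theta=-57.0,
                                      sequence_a="AAAAAAAKAAAAAA"))


@pytest.fixture(scope="session")
def corner_pair_helices(corner_pair):
    from ptmstruct import assign_helices
    return assign_helices(place_amide_hydrogens(corner_pair.structure))


def random_axis(rng: np.random.Generator, span: float = 20.0) -> HelixAxis:
    """A random finite axis segment for geometry property tests."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    length = rng.uniform(5.0, 30.0)
    return HelixAxis(anchor=rng.uniform(-span, span, size=3),
                     direction=direction, seg_start=0.0, seg_end=length,
                     radius=rng.uniform(2.0, 5.0), fit_rmsd=0.0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
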