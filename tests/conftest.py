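import numpy as np
import pytest

from pacrys import LatticeParameters
from pacrys.fixtures import FixtureSpec, make_crystal

FIXTURE_GROUPS = ["P 1", "P -1", "P 21", "P 21/c", "P 21 21 21"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def bent_crystals():
    """One bent-molecule crystal per supported space group."""
    return {g: make_crystal(FixtureSpec(molecule_shape="bent", space_group=g, seed=5))
            for g in FIXTURE_GROUPS}


@pytest.fixture(scope="session")
def p21_crystal(bent_crystals):
    return bent_crystals["P 21"]


@pytest.fixture(scope="session")
def z2_crystal():
    """Bent molecule, P 21, two molecules in the asymmetric unit."""
    return make_crystal(FixtureSpec(
        molecule_shape="bent", space_group="P 21", z_prime=2, seed=6,
        lattice=LatticeParameters(12.0, 13.0, 11.5, 90, 101, 90)))


@pytest.fixture(scope="session")
def chiral_p21c_crystal():
    """Chiral molecule in the enantiogenic group P 21/c."""
    return make_crystal(FixtureSpec(
        molecule_shape="tetra_chiral", space_group="P 21/c", seed=2))


@pytest.fixture(scope="session")
def rod_crystal():
    """Elongated zigzag molecules stacked tightly end-to-end along a."""
    return make_crystal(FixtureSpec(
        molecule_shape="rod", space_group="P 1",
        lattice=LatticeParameters(8.2, 5.0, 5.5, 90, 90, 90), seed=1))


def kabsch_rmsd(ref, mov, weights=None):
    """Independent SVD-based (Kabsch) oracle for the minimal proper-rotation
    weighted RMSD."""
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    w = np.ones(len(ref)) if weights is None else np.asarray(weights, float)
    P = ref - w @ ref / w.sum()
    Q = mov - w @ mov / w.sum()
    H = (w[:, None] * Q).T @ P
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = Q @ R.T - P
    return float(np.sqrt(w @ np.einsum("ij,ij->i", diff, diff) / w.sum()))
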