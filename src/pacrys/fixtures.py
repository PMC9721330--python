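"""Deterministic synthetic crystals for testing and demonstration.

Real reference crystals cannot be bundled, so every pipeline input is built
here: rigid toy molecules placed into small cells of common space groups
(P1, P-1, P21, P21/c, P212121), with optional coordinate noise, lattice
scaling and crystallographically equivalent re-descriptions (origin shift,
rotated setting, P1 supercell).  Molecules are rigid frames with no internal
degrees of freedom, so ground-truth congruence between symmetry copies is
exact and every test has an analytic expectation.  A single integer seed
drives one :class:`numpy.random.Generator`; the same spec and seed always
produce byte-identical crystals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AsymmetricUnit,
    Crystal,
    LatticeParameters,
    SpaceGroup,
    SymmetryOperator,
    cart_to_frac,
    frac_to_cart,
)

__all__ = [
    "FixtureSpec",
    "MOLECULE_SHAPES",
    "SUPPORTED_GROUPS",
    "make_crystal",
    "perturb_crystal",
    "reexpress_crystal",
]

# Rigid toy molecules: (elements, names, coordinates in Å).  Shapes are chosen
# to exercise distinct geometry classes: an elongated rod, a bent planar
# frame, a chiral tetrahedral center with four distinct arms, and a strictly
# planar (hence achiral) frame.
MOLECULE_SHAPES = {
    # Slight zigzag so the rod is elongated but not collinear (a collinear
    # molecule would leave single-molecule superposition under-determined).
    "rod": (
        ["C", "C", "C", "C", "N"],
        [[0.0, 0.25, 0.0], [1.35, -0.25, 0.0], [2.70, 0.25, 0.0],
         [4.05, -0.25, 0.0], [5.35, 0.25, 0.0]],
    ),
    "bent": (
        ["C", "C", "O", "N"],
        [[0.0, 0.0, 0.0], [1.45, 0.0, 0.0], [2.15, 1.15, 0.0], [-0.65, 1.20, 0.0]],
    ),
    "tetra_chiral": (
        ["C", "N", "O", "S", "Cl"],
        [[0.0, 0.0, 0.0],
         [0.75, 0.75, 0.75],       # N arm, 1.30 Å
         [0.70, -0.70, -0.70],     # O arm, 1.21 Å
         [-1.05, 1.05, -1.05],     # S arm, 1.82 Å
         [-1.00, -1.00, 1.00]],    # Cl arm, 1.73 Å
    ),
    "planar_achiral": (
        ["C", "O", "N", "C"],
        [[0.0, 0.0, 0.0], [1.25, 0.35, 0.0], [-0.70, 1.10, 0.0], [-0.55, -1.30, 0.0]],
    ),
    # Acetamide-like molecule with hydrogens, for atom-selection tests:
    # 4 heavy atoms (C, C, N, O) + 5 H.
    "acetamide": (
        ["C", "C", "N", "O", "H", "H", "H", "H", "H"],
        [[0.0, 0.0, 0.0], [1.51, 0.0, 0.0], [2.18, 1.15, 0.0], [2.10, -1.05, 0.0],
         [-0.40, 1.00, 0.0], [-0.40, -0.50, 0.88], [-0.40, -0.50, -0.88],
         [3.18, 1.18, 0.05], [1.72, 2.02, -0.05]],
    ),
}

SUPPORTED_GROUPS = {
    "P 1": "P 1",
    "P -1": "P -1",
    "P 21": "P 1 21 1",
    "P 21/c": "P 1 21/c 1",
    "P 21 21 21": "P 21 21 21",
}

# Roomy default cells so random placement clears the steric check quickly.
_DEFAULT_LATTICES = {
    "P 1": LatticeParameters(9.0, 8.0, 8.5, 85.0, 95.0, 92.0),
    "P -1": LatticeParameters(9.5, 9.0, 10.0, 88.0, 96.0, 91.0),
    "P 21": LatticeParameters(9.5, 10.5, 9.0, 90.0, 101.0, 90.0),
    "P 21/c": LatticeParameters(10.5, 11.5, 11.0, 90.0, 104.0, 90.0),
    "P 21 21 21": LatticeParameters(10.0, 11.0, 12.0, 90.0, 90.0, 90.0),
}

_MIN_CONTACT = 1.5  # Å; minimal allowed intermolecular atom distance
_MAX_RETRIES = 300


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic crystal."""

    molecule_shape: str = "bent"
    space_group: str = "P 1"
    lattice: LatticeParameters | None = None
    z_prime: int = 1
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.molecule_shape not in MOLECULE_SHAPES:
            raise ValueError(f"unknown molecule shape: {self.molecule_shape!r}")
        if self.space_group not in SUPPORTED_GROUPS:
            raise ValueError(
                f"unsupported space group {self.space_group!r}; "
                f"choose from {sorted(SUPPORTED_GROUPS)}"
            )
        if self.z_prime < 1:
            raise ValueError("z_prime must be >= 1")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    q0, q1, q2, q3 = q
    return np.array(
        [
            [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
        ]
    )


def _steric_clash(crystal: Crystal) -> bool:
    """True if any two distinct molecules in a 3x3x3 cell block come closer
    than the contact floor."""
    from scipy.spatial.distance import cdist

    au = crystal.asymmetric_unit
    lattice = crystal.lattice
    groups = []
    for op_i, op in enumerate(crystal.space_group.operators):
        for mol_i, idx in enumerate(au.molecules):
            frac = cart_to_frac(lattice, au.coords[idx])
            moved = op.apply(frac)
            moved -= np.floor(moved.mean(axis=0))
            for shift in np.ndindex(3, 3, 3):
                s = np.asarray(shift) - 1
                groups.append(frac_to_cart(lattice, moved + s))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            # same molecule copy at identical position (special cases) is a clash too
            if cdist(groups[i], groups[j]).min() < _MIN_CONTACT:
                return True
    return False


def make_crystal(spec: FixtureSpec) -> Crystal:
    """Build a synthetic crystal from a spec, deterministically under its seed.

    Each of the Z' molecules gets a random orientation and fractional
    position; placements are retried until all intermolecular contacts in the
    expanded cell exceed 1.5 Å.
    """
    elements, template = MOLECULE_SHAPES[spec.molecule_shape]
    template = np.asarray(template, dtype=float)
    template = template - template.mean(axis=0)
    lattice = spec.lattice or _DEFAULT_LATTICES[spec.space_group]
    sg = SpaceGroup.from_symbol(SUPPORTED_GROUPS[spec.space_group])
    rng = np.random.default_rng(spec.seed)
    names = [f"{el}{i + 1}" for i, el in enumerate(elements)]

    for _attempt in range(_MAX_RETRIES):
        coords, molecules = [], []
        for m in range(spec.z_prime):
            rot = _random_rotation(rng)
            pos_frac = rng.uniform(0.1, 0.9, size=3)
            placed = template @ rot.T + frac_to_cart(lattice, pos_frac)
            start = len(elements) * m
            molecules.append(np.arange(start, start + len(elements)))
            coords.append(placed)
        au = AsymmetricUnit(
            elements=list(elements) * spec.z_prime,
            coords=np.concatenate(coords),
            molecules=molecules,
            names=names * spec.z_prime,
        )
        crystal = Crystal(
            lattice=lattice, space_group=sg, asymmetric_unit=au,
            name=spec.name or f"{spec.molecule_shape}_{spec.space_group.replace(' ', '')}_s{spec.seed}",
        )
        if not _steric_clash(crystal):
            return crystal
    raise RuntimeError(
        f"could not place {spec.z_prime} molecule(s) without contacts < "
        f"{_MIN_CONTACT} Å after {_MAX_RETRIES} tries; use a larger cell"
    )


def perturb_crystal(crystal: Crystal, sigma_coord: float = 0.0,
                    lattice_scale: float = 1.0, seed: int = 0) -> Crystal:
    """Noisy/strained copy of a crystal.

    Adds i.i.d. Gaussian noise (σ = ``sigma_coord`` Å) to every
    asymmetric-unit Cartesian coordinate and multiplies the cell edges by
    ``lattice_scale``.  The same seed draws the same unit noise, so noise at
    different σ is directly comparable.
    """
    if sigma_coord < 0:
        raise ValueError("sigma_coord must be >= 0")
    if lattice_scale <= 0:
        raise ValueError("lattice_scale must be > 0")
    rng = np.random.default_rng(seed)
    au = crystal.asymmetric_unit
    noise = rng.standard_normal(au.coords.shape)
    frac = cart_to_frac(crystal.lattice, au.coords)
    new_lattice = crystal.lattice.scaled(lattice_scale)
    new_coords = frac_to_cart(new_lattice, frac) + sigma_coord * noise
    new_au = AsymmetricUnit(
        elements=list(au.elements), coords=new_coords,
        molecules=[m.copy() for m in au.molecules],
        names=list(au.names) if au.names else None,
    )
    return Crystal(lattice=new_lattice, space_group=crystal.space_group,
                   asymmetric_unit=new_au, name=crystal.name + "_perturbed")


def _basis_change(crystal: Crystal, P: np.ndarray) -> Crystal:
    """Re-express a crystal in a new lattice basis C' = C @ P.

    P columns give the new lattice vectors in old fractional coordinates and
    must carry every symmetry operator to an integer matrix in the new basis.
    """
    C = crystal.lattice.cell_matrix
    Cp = C @ P
    a, b, c = (np.linalg.norm(Cp[:, i]) for i in range(3))

    def angle(u, v):
        return float(np.degrees(np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))))

    new_lattice = LatticeParameters(a, b, c,
                                    angle(Cp[:, 1], Cp[:, 2]),
                                    angle(Cp[:, 0], Cp[:, 2]),
                                    angle(Cp[:, 0], Cp[:, 1]))
    Pinv = np.linalg.inv(P)
    new_ops = []
    for op in crystal.space_group.operators:
        R = Pinv @ op.rotation @ P
        if not np.allclose(R, np.round(R), atol=1e-9):
            raise ValueError("basis change does not preserve the symmetry operators")
        new_ops.append(SymmetryOperator(np.round(R), Pinv @ op.translation))
    sg = SpaceGroup(number=crystal.space_group.number,
                    symbol=crystal.space_group.symbol + " (alt)",
                    operators=new_ops)
    au = crystal.asymmetric_unit
    frac = cart_to_frac(crystal.lattice, au.coords)
    new_coords = frac_to_cart(new_lattice, frac @ Pinv.T)
    new_au = AsymmetricUnit(elements=list(au.elements), coords=new_coords,
                            molecules=[m.copy() for m in au.molecules],
                            names=list(au.names) if au.names else None)
    return Crystal(lattice=new_lattice, space_group=sg, asymmetric_unit=new_au,
                   name=crystal.name + "_alt")


def reexpress_crystal(crystal: Crystal, mode: str, seed: int = 0) -> Crystal:
    """A crystallographically equivalent description of the same packing.

    ``origin_shift`` translates the asymmetric unit by an allowed origin
    shift (arbitrary for P1, (1/2, 1/2, 1/2) otherwise — valid for all
    supported groups).  ``rotated_setting`` re-expresses the lattice in the
    basis a' = a + c, which rigidly rotates the Cartesian frame.
    ``supercell_2x1x1`` lists every molecule of a doubled cell explicitly in
    P1.  All three should compare to the original at RMSD_N ≈ 0.
    """
    au = crystal.asymmetric_unit
    if mode == "origin_shift":
        if crystal.space_group.order == 1 and crystal.space_group.is_sohncke:
            shift = np.random.default_rng(seed).uniform(0.05, 0.95, size=3)
        else:
            shift = np.array([0.5, 0.5, 0.5])
        new_coords = au.coords + frac_to_cart(crystal.lattice, shift)
        new_au = AsymmetricUnit(elements=list(au.elements), coords=new_coords,
                                molecules=[m.copy() for m in au.molecules],
                                names=list(au.names) if au.names else None)
        return Crystal(lattice=crystal.lattice, space_group=crystal.space_group,
                       asymmetric_unit=new_au, name=crystal.name + "_shifted")

    if mode == "rotated_setting":
        P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        return _basis_change(crystal, P)

    if mode == "supercell_2x1x1":
        lattice = crystal.lattice
        elements, coords, molecules, names = [], [], [], []
        for cell_shift in ((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)):
            for op in crystal.space_group.operators:
                for idx in au.molecules:
                    frac = cart_to_frac(lattice, au.coords[idx])
                    moved = op.apply(frac)
                    moved -= np.floor(moved.mean(axis=0))
                    moved += np.asarray(cell_shift)
                    start = len(elements)
                    elements.extend(au.elements[i] for i in idx)
                    if au.names:
                        names.extend(au.names[i] for i in idx)
                    coords.append(frac_to_cart(lattice, moved))
                    molecules.append(np.arange(start, start + len(idx)))
        new_lattice = LatticeParameters(lattice.a * 2, lattice.b, lattice.c,
                                        lattice.alpha, lattice.beta, lattice.gamma)
        new_au = AsymmetricUnit(elements=elements, coords=np.concatenate(coords),
                                molecules=molecules, names=names or None)
        sg = SpaceGroup(number=1, symbol="P 1",
                        operators=[SymmetryOperator.identity()])
        return Crystal(lattice=new_lattice, space_group=sg,
                       asymmetric_unit=new_au, name=crystal.name + "_super211")

    raise ValueError(f"unknown re-expression mode: {mode!r}")
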