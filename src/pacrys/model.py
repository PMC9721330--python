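"""Core crystallographic data types and lattice geometry.

A crystal is described by its lattice parameters, its space group and the
Cartesian coordinates of the molecules in the asymmetric unit.  All other
modules consume these types; nothing here touches files.

Cartesianization convention: the **a** axis lies along *x* and **b** lies in
the *x*-*y* plane.  The convention is arbitrary — every comparison downstream
happens in Cartesian space — but it is fixed so that fractional/Cartesian
round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "InvalidLatticeError",
    "LatticeParameters",
    "SymmetryOperator",
    "SpaceGroup",
    "AsymmetricUnit",
    "Crystal",
    "unit_cell_volume",
    "frac_to_cart",
    "cart_to_frac",
    "expected_cluster_volume",
    "atomic_mass",
    "covalent_radius",
]


class InvalidLatticeError(ValueError):
    """Raised for degenerate or out-of-range lattice parameters."""


def atomic_mass(element: str) -> float:
    """Standard atomic weight (Da) for an element symbol."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol: {element!r}")
    return float(el.weight)


def covalent_radius(element: str) -> float:
    """Covalent radius (Å) for an element symbol."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol: {element!r}")
    return float(el.covalent_r)


@dataclass(frozen=True)
class LatticeParameters:
    """Unit-cell edge lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidLatticeError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidLatticeError("cell angles must lie in (0, 180)")
        if self._radicand() <= 0:
            raise InvalidLatticeError("degenerate cell (zero or negative volume)")

    def _radicand(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return float(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)

    @property
    def cell_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the lattice vectors a, b, c."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(self._radicand())
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.cell_matrix)

    def scaled(self, factor: float) -> "LatticeParameters":
        """Same angles, edges multiplied by ``factor``."""
        return LatticeParameters(
            self.a * factor, self.b * factor, self.c * factor,
            self.alpha, self.beta, self.gamma,
        )


def unit_cell_volume(lattice: LatticeParameters) -> float:
    """Unit-cell volume in Å³ from the closed-form triclinic expression."""
    return float(lattice.a * lattice.b * lattice.c * np.sqrt(lattice._radicand()))


def frac_to_cart(lattice: LatticeParameters, frac: np.ndarray) -> np.ndarray:
    """Map fractional coordinates (..., 3) to Cartesian Å."""
    return np.asarray(frac, dtype=float) @ lattice.cell_matrix.T


def cart_to_frac(lattice: LatticeParameters, cart: np.ndarray) -> np.ndarray:
    """Inverse of :func:`frac_to_cart`."""
    return np.asarray(cart, dtype=float) @ lattice.inverse_matrix.T


class SymmetryOperator:
    """One space-group operator acting on fractional coordinates.

    ``rotation`` is an integer-valued 3x3 matrix (determinant ±1) and
    ``translation`` a fractional 3-vector with components in [0, 1).
    """

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation, translation) -> None:
        rot = np.asarray(rotation, dtype=float)
        if rot.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(rot, np.round(rot), atol=1e-9):
            raise ValueError("rotation part must be integer-valued")
        det = round(float(np.linalg.det(rot)))
        if det not in (-1, 1):
            raise ValueError(f"rotation determinant must be ±1, got {det}")
        self.rotation = np.round(rot).astype(int)
        self.translation = np.mod(np.asarray(translation, dtype=float), 1.0)

    @property
    def is_proper(self) -> bool:
        return round(float(np.linalg.det(self.rotation))) == 1

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates of shape (..., 3)."""
        return np.asarray(frac, dtype=float) @ self.rotation.T.astype(float) + self.translation

    def __eq__(self, other) -> bool:
        if not isinstance(other, SymmetryOperator):
            return NotImplemented
        return bool(
            np.array_equal(self.rotation, other.rotation)
            and np.allclose(self.translation, other.translation, atol=1e-9)
        )

    def __hash__(self) -> int:
        return hash((self.rotation.tobytes(), tuple(np.round(self.translation * 24).astype(int))))

    def __repr__(self) -> str:
        return f"SymmetryOperator(rot={self.rotation.tolist()}, tran={self.translation.tolist()})"

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(np.eye(3, dtype=int), np.zeros(3))

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymmetryOperator":
        den = float(gemmi.Op.DEN)
        return cls(np.array(op.rot, dtype=float) / den, np.array(op.tran, dtype=float) / den)

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOperator":
        """Parse an ``x,y,z``-style triplet (e.g. ``-x, y+1/2, -z``)."""
        return cls.from_gemmi(gemmi.Op(triplet))


@dataclass
class SpaceGroup:
    """A space group as an explicit operator list (centering pre-expanded).

    ``is_sohncke`` is true iff every operator is a proper rotation, in which
    case the crystal cannot contain the mirror image of its asymmetric unit.
    """

    number: int
    symbol: str
    operators: list = field(default_factory=lambda: [SymmetryOperator.identity()])

    def __post_init__(self) -> None:
        if not any(op == SymmetryOperator.identity() for op in self.operators):
            raise ValueError("operator list must contain the identity")

    @property
    def order(self) -> int:
        return len(self.operators)

    @property
    def is_sohncke(self) -> bool:
        return all(op.is_proper for op in self.operators)

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroup":
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unknown space-group symbol: {symbol!r}")
        return cls._from_gemmi(sg)

    @classmethod
    def from_number(cls, number: int) -> "SpaceGroup":
        sg = gemmi.find_spacegroup_by_number(number)
        if sg is None:
            raise ValueError(f"unknown space-group number: {number}")
        return cls._from_gemmi(sg)

    @classmethod
    def from_operators(cls, triplets, symbol: str = "?", number: int = 0) -> "SpaceGroup":
        ops = [
            t if isinstance(t, SymmetryOperator) else SymmetryOperator.from_xyz(t)
            for t in triplets
        ]
        return cls(number=number, symbol=symbol, operators=ops)

    @classmethod
    def _from_gemmi(cls, sg: gemmi.SpaceGroup) -> "SpaceGroup":
        ops = [SymmetryOperator.from_gemmi(op) for op in sg.operations()]
        return cls(number=sg.number, symbol=sg.hm, operators=ops)


@dataclass
class AsymmetricUnit:
    """Atoms of the asymmetric unit, partitioned into Z' molecules.

    ``coords`` are Cartesian (Å).  ``molecules`` holds index arrays into the
    atom list; every atom belongs to exactly one molecule.
    """

    elements: list
    coords: np.ndarray
    molecules: list
    masses: np.ndarray | None = None
    names: list | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        self.molecules = [np.asarray(m, dtype=int) for m in self.molecules]
        seen = np.concatenate(self.molecules) if self.molecules else np.array([], dtype=int)
        if sorted(seen.tolist()) != list(range(len(self.elements))):
            raise ValueError("molecules must partition the atom indices")
        if self.masses is None:
            self.masses = np.array([atomic_mass(e) for e in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def z_prime(self) -> int:
        return len(self.molecules)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Crystal:
    """A crystal: lattice + space group + asymmetric unit."""

    lattice: LatticeParameters
    space_group: SpaceGroup
    asymmetric_unit: AsymmetricUnit
    name: str = "crystal"

    def __post_init__(self) -> None:
        frac = cart_to_frac(self.lattice, self.asymmetric_unit.coords)
        if frac.size and np.abs(frac).max() >= 10:
            raise ValueError(
                "asymmetric-unit coordinates are implausibly far from the cell "
                f"(|frac| up to {np.abs(frac).max():.1f})"
            )

    @property
    def z_prime(self) -> int:
        return self.asymmetric_unit.z_prime

    @property
    def molecules_per_cell(self) -> int:
        return self.z_prime * self.space_group.order


def expected_cluster_volume(crystal: Crystal, n: int) -> float:
    """Expected volume (Å³) of an *n*-molecule cluster.

    The unit-cell volume divided by the number of molecules the cell contains,
    times *n*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return unit_cell_volume(crystal.lattice) / crystal.molecules_per_cell * n
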