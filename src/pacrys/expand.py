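"""Symmetry expansion of the asymmetric unit into a sphere of whole molecules.

The asymmetric-unit molecules are replicated by the space-group operators and
a centered block of lattice translations until the expansion holds enough
material for cluster selection — by default six times the expected cluster
volume, counted as molecules (replicating whole cells makes molecule count an
exact volume proxy).  Each copy is produced by transforming a source molecule
rigidly and wrapping its *center* back into the home cell by whole lattice
translations, so molecules are never shredded across cell boundaries.
Molecules are then ranked by the distance of their geometric center from the
grand center of all expanded atoms; the unique molecular conformations are
identified in that priority order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AtomSelection, ResolvedSelection, resolve_selection
from .model import Crystal, cart_to_frac, frac_to_cart
from .superpose import quaternion_superpose

__all__ = [
    "MoleculeInstance",
    "ExpandedCrystal",
    "expand_crystal",
    "find_unique_conformers",
    "pair_conformers",
]

#: RMSD_1 below which two molecule copies count as the same conformation (Å).
DEFAULT_CONFORMER_TOL = 0.1


@dataclass
class MoleculeInstance:
    """One whole-molecule copy in the expansion (selected atoms only)."""

    source_molecule: int
    operator_id: int
    lattice_shift: tuple[int, int, int]
    coords: np.ndarray
    center: np.ndarray


@dataclass
class ExpandedCrystal:
    """A finite sphere of molecule copies, ranked by distance from its grand center."""

    molecules: list
    grand_center: np.ndarray
    source: Crystal
    selection: ResolvedSelection
    n_target: int
    volume_scalar: float

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def centers(self) -> np.ndarray:
        return np.array([m.center for m in self.molecules])

    def coords_of(self, indices) -> np.ndarray:
        """Concatenated selected-atom coordinates of the given molecules."""
        return np.concatenate([self.molecules[i].coords for i in indices])

    def weights_of(self, indices) -> np.ndarray:
        w = self.selection.weights
        return np.concatenate([w[self.molecules[i].source_molecule] for i in indices])

    def elements_of(self, indices) -> list:
        els = self.selection.elements
        return [e for i in indices for e in els[self.molecules[i].source_molecule]]


def _block_dimensions(lattice, n_cells: int, radius: float) -> tuple[int, int, int]:
    """Centered (odd-edge) block of unit cells for the expansion.

    The block must both hold at least ``n_cells`` cells and cover a sphere of
    the given ``radius`` around its center, whatever the cell shape.  The
    covering condition uses the interplanar spacings (slab thicknesses) of
    the three axis directions; axes are grown anisotropically — always the
    one whose slab extent is currently smallest — so the block stays roughly
    isometric and the grand center stays interior.
    """
    ginv = lattice.inverse_matrix
    spacing = 1.0 / np.linalg.norm(ginv, axis=1)  # slab thickness per axis
    half = [max(0, math.ceil(radius / spacing[i] - 0.5)) for i in range(3)]
    while (2 * half[0] + 1) * (2 * half[1] + 1) * (2 * half[2] + 1) < n_cells:
        extents = [(2 * half[i] + 1) * spacing[i] for i in range(3)]
        half[extents.index(min(extents))] += 1
    return tuple(2 * h + 1 for h in half)


def expand_crystal(crystal: Crystal, n: int, selection: AtomSelection | None = None,
                   volume_scalar: float = 6.0, min_radius: float | None = None) -> ExpandedCrystal:
    """Expand a crystal so it holds at least ``volume_scalar * n * Z'`` molecules.

    ``n`` is the cluster size in asymmetric units; the default scalar of six
    leaves ample material around the final cluster.  The result is sorted by
    center distance from the grand geometric center of all expanded atoms,
    with ties broken by (operator, lattice shift, source molecule) for
    determinism.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    resolved = selection if isinstance(selection, ResolvedSelection) \
        else resolve_selection(crystal, selection)

    au = crystal.asymmetric_unit
    lattice = crystal.lattice
    ops = crystal.space_group.operators
    budget = int(math.ceil(volume_scalar * n * au.z_prime))

    # Home copies: every (operator, source molecule), center wrapped to [0, 1).
    home = []  # (source_molecule, operator_id, base_shift, frac_coords)
    for mol_i, idx in enumerate(resolved.molecule_indices):
        frac = cart_to_frac(lattice, au.coords[idx])
        for op_i, op in enumerate(ops):
            moved = op.apply(frac)
            wrap = -np.floor(moved.mean(axis=0))
            home.append((mol_i, op_i, wrap.astype(int), moved + wrap))

    # The block must hold the molecule budget and, geometrically, cover a
    # sphere of volume_scalar times the expected cluster volume (plus a
    # one-cell margin) around its center: cluster selection happens around
    # the center-most molecule, which can sit up to about half a cell away
    # from the block center.
    from .model import expected_cluster_volume

    cells_needed = math.ceil(budget / len(home))
    v_target = volume_scalar * expected_cluster_volume(crystal, n * au.z_prime)
    corners = lattice.cell_matrix @ (np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1])).reshape(3, -1) * 0.5)
    half_diag = float(np.linalg.norm(corners, axis=0).max())
    radius = (3.0 * v_target / (4.0 * np.pi)) ** (1.0 / 3.0) + half_diag
    if min_radius is not None:
        radius = max(radius, min_radius)
    dims = _block_dimensions(lattice, cells_needed, radius)
    shifts = [
        (i, j, k)
        for i in range(-(dims[0] // 2), dims[0] // 2 + 1)
        for j in range(-(dims[1] // 2), dims[1] // 2 + 1)
        for k in range(-(dims[2] // 2), dims[2] // 2 + 1)
    ]

    cell = lattice.cell_matrix
    instances = []
    for shift in shifts:
        shift_cart = cell @ np.asarray(shift, dtype=float)
        for mol_i, op_i, wrap, frac in home:
            coords = frac_to_cart(lattice, frac) + shift_cart
            total_shift = tuple(int(x) for x in (np.asarray(shift) + wrap))
            instances.append(MoleculeInstance(
                source_molecule=mol_i,
                operator_id=op_i,
                lattice_shift=total_shift,
                coords=coords,
                center=coords.mean(axis=0),
            ))

    atom_counts = np.array([len(m.coords) for m in instances], dtype=float)
    centers = np.array([m.center for m in instances])
    grand_center = (atom_counts @ centers) / atom_counts.sum()

    dist = np.linalg.norm(centers - grand_center, axis=1)
    keys = sorted(
        range(len(instances)),
        key=lambda i: (
            round(dist[i], 9),
            instances[i].operator_id,
            instances[i].lattice_shift,
            instances[i].source_molecule,
        ),
    )
    ordered = [instances[i] for i in keys]
    return ExpandedCrystal(
        molecules=ordered,
        grand_center=grand_center,
        source=crystal,
        selection=resolved,
        n_target=n,
        volume_scalar=volume_scalar,
    )


def find_unique_conformers(expanded: ExpandedCrystal,
                           tolerance: float = DEFAULT_CONFORMER_TOL) -> list:
    """Representative molecule indices of the unique conformations.

    Walks the molecules in center-distance order; a molecule starts a new
    conformation when its best proper-rotation superposition RMSD_1 onto every
    existing representative exceeds ``tolerance``.  For rigid molecules the
    count is bounded by Z' in Sohncke groups and 2 Z' otherwise, so scanning
    stops once that bound is reached.
    """
    if len(expanded) == 0:
        raise ValueError("expansion is empty")
    z = expanded.source.z_prime
    bound = z if expanded.source.space_group.is_sohncke else 2 * z
    reps: list[int] = []
    for i, mol in enumerate(expanded.molecules):
        new = True
        for r in reps:
            ref = expanded.molecules[r]
            if ref.coords.shape != mol.coords.shape:
                continue
            w = expanded.weights_of([r])
            if quaternion_superpose(ref.coords, mol.coords, w).rmsd <= tolerance:
                new = False
                break
        if new:
            reps.append(i)
            if len(reps) >= bound:
                break
    return reps


def pair_conformers(expanded1: ExpandedCrystal, reps1,
                    expanded2: ExpandedCrystal, reps2) -> list:
    """All cross pairs of unique-conformer representatives, by ascending RMSD_1.

    Returns (index into expansion 1, index into expansion 2, rmsd_1) triples;
    these are the seeds the progressive alignment is repeated over.
    """
    if not reps1 or not reps2:
        raise ValueError("both crystals need at least one unique conformer")
    pairs = []
    for i in reps1:
        for j in reps2:
            a = expanded1.molecules[i]
            b = expanded2.molecules[j]
            if a.coords.shape != b.coords.shape:
                raise ValueError(
                    "selected atom counts differ between crystals "
                    f"({len(a.coords)} vs {len(b.coords)})"
                )
            w = expanded1.weights_of([i])
            pairs.append((i, j, quaternion_superpose(a.coords, b.coords, w).rmsd))
    pairs.sort(key=lambda t: (t[2], t[0], t[1]))
    return pairs
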