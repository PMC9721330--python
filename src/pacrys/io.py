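"""Crystal input/output: CIF and PDB readers, cluster writers, atom selection.

CIF files (small molecules) supply fractional atom sites plus a symmetry loop
or a space-group symbol; PDB files (macromolecules) supply Cartesian sites
plus a CRYST1 record.  Both are parsed with :mod:`gemmi`.  Waters and
non-polymer co-solutes are dropped from PDB input by default, and each chain
becomes one molecule of the asymmetric unit.  For CIF input molecules are
found as covalently connected components.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .model import (
    AsymmetricUnit,
    Crystal,
    LatticeParameters,
    SpaceGroup,
    cart_to_frac,
    covalent_radius,
    frac_to_cart,
)

__all__ = [
    "ParseError",
    "AtomSelection",
    "ResolvedSelection",
    "read_cif",
    "read_pdb",
    "read_crystal",
    "write_cif",
    "write_cluster",
    "partition_molecules",
    "resolve_selection",
]

#: Residue names treated as solvent/co-solute and removed from PDB input.
SOLVENT_RESIDUES = {"HOH", "DOD", "WAT", "SO4", "PO4", "GOL", "EDO", "PEG", "ACT", "DMS", "CL", "NA", "K", "MG", "ZN", "CA2"}

# Extra slack added to the sum of covalent radii when deciding bonding.
BOND_TOLERANCE = 0.4


class ParseError(ValueError):
    """Raised when a structure file lacks a required item."""


@dataclass
class AtomSelection:
    """Which atoms enter the comparison and how they are weighted.

    ``heavy`` (the default) drops hydrogen and deuterium: experimental H
    positions are usually the least certain.  ``alpha_carbon`` keeps CA atoms
    only (proteins).  Mass weighting is off by default so that third-period
    and heavier elements are not over-prioritized relative to C/N/O.
    """

    mode: str = "heavy"
    custom_indices: list | None = None
    mass_weighted: bool = False

    def __post_init__(self) -> None:
        if self.mode not in {"heavy", "alpha_carbon", "all", "custom"}:
            raise ValueError(f"unknown selection mode: {self.mode!r}")
        if self.mode == "custom" and not self.custom_indices:
            raise ValueError("custom selection requires custom_indices")


@dataclass
class ResolvedSelection:
    """Per-molecule atom indices (into the asymmetric unit) plus weights."""

    molecule_indices: list
    weights: list
    elements: list

    @property
    def atoms_per_molecule(self) -> int:
        return len(self.molecule_indices[0]) if self.molecule_indices else 0


def resolve_selection(crystal: Crystal, selection: AtomSelection | None = None) -> ResolvedSelection:
    """Resolve an :class:`AtomSelection` against one crystal.

    Returns index lists per asymmetric-unit molecule, in a consistent order,
    together with the fitting weights (unit, or atomic masses when mass
    weighting was requested).
    """
    selection = selection or AtomSelection()
    au = crystal.asymmetric_unit
    mol_idx, weights, elements = [], [], []
    for mol in au.molecules:
        if selection.mode == "all":
            keep = mol
        elif selection.mode == "heavy":
            keep = np.array([i for i in mol if au.elements[i] not in ("H", "D")], dtype=int)
        elif selection.mode == "alpha_carbon":
            if au.names is None:
                raise ValueError("alpha_carbon selection requires atom-name labels")
            keep = np.array([i for i in mol if au.names[i].strip() == "CA"], dtype=int)
        else:  # custom
            wanted = set(selection.custom_indices)
            keep = np.array([i for i in mol if i in wanted], dtype=int)
        if len(keep) == 0:
            raise ValueError(f"selection {selection.mode!r} leaves no atoms in a molecule")
        mol_idx.append(keep)
        if selection.mass_weighted:
            weights.append(au.masses[keep])
        else:
            weights.append(np.ones(len(keep)))
        elements.append([au.elements[i] for i in keep])
    return ResolvedSelection(mol_idx, weights, elements)


def partition_molecules(elements, coords, bond_tolerance: float = BOND_TOLERANCE) -> list:
    """Partition atoms into molecules as covalent connected components.

    Two atoms bond when their distance is at most the sum of covalent radii
    plus ``bond_tolerance`` Å.  Components are ordered by their smallest atom
    index.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return []
    radii = np.array([covalent_radius(e) for e in elements])
    dist = cdist(pts, pts)
    cutoff = radii[:, None] + radii[None, :] + bond_tolerance
    adj = csr_matrix((dist <= cutoff) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    groups = [np.flatnonzero(labels == k) for k in range(n_comp)]
    groups.sort(key=lambda g: int(g[0]))
    return groups


# ---------------------------------------------------------------------------
# CIF

_CELL_TAGS = ("_cell_length_a", "_cell_length_b", "_cell_length_c",
              "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma")
_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")
_SYMBOL_TAGS = ("_space_group_name_H-M_alt", "_symmetry_space_group_name_H-M")


def _cif_number(block: gemmi.cif.Block, tag: str) -> float:
    val = block.find_value(tag)
    if val is None:
        raise ParseError(f"CIF is missing {tag}")
    return gemmi.cif.as_number(val)


def read_cif(path) -> Crystal:
    """Read a small-molecule crystal from a CIF file.

    Symmetry operators are taken from the symmetry loop when present (files
    are authoritative); otherwise the space group is resolved from the
    Hermann-Mauguin symbol or IT number.
    """
    doc = gemmi.cif.read_file(os.fspath(path))
    block = doc.sole_block()

    lattice = LatticeParameters(*(_cif_number(block, t) for t in _CELL_TAGS))

    sg = None
    for tag in _SYMOP_TAGS:
        triplets = list(block.find_loop(tag))
        if triplets:
            symbol = next((gemmi.cif.as_string(v) for t in _SYMBOL_TAGS
                           if (v := block.find_value(t)) is not None), "?")
            sg = SpaceGroup.from_operators(
                [gemmi.cif.as_string(t) for t in triplets], symbol=symbol
            )
            break
    if sg is None:
        for tag in _SYMBOL_TAGS:
            val = block.find_value(tag)
            if val is not None:
                sg = SpaceGroup.from_symbol(gemmi.cif.as_string(val))
                break
    if sg is None:
        val = block.find_value("_space_group_IT_number") or block.find_value("_symmetry_Int_Tables_number")
        if val is not None:
            sg = SpaceGroup.from_number(int(gemmi.cif.as_number(val)))
    if sg is None:
        raise ParseError("CIF is missing symmetry (no symop loop, H-M symbol or IT number)")

    table = block.find("_atom_site_", ["type_symbol", "fract_x", "fract_y", "fract_z"])
    labels = list(block.find_loop("_atom_site_label"))
    if len(table) == 0:
        table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
        if len(table) == 0:
            raise ParseError("CIF is missing atom sites (_atom_site_fract_* loop)")
        elements = [_element_from_label(gemmi.cif.as_string(r[0])) for r in table]
    else:
        elements = [gemmi.cif.as_string(r[0]) for r in table]
    frac = np.array([[gemmi.cif.as_number(r[i]) for i in (1, 2, 3)] for r in table])
    coords = frac_to_cart(lattice, frac)
    names = [gemmi.cif.as_string(l) for l in labels] if len(labels) == len(elements) else None

    molecules = partition_molecules(elements, coords)
    au = AsymmetricUnit(elements=elements, coords=coords, molecules=molecules, names=names)
    name = block.name if block.name and block.name != "#" else os.path.basename(os.fspath(path))
    return Crystal(lattice=lattice, space_group=sg, asymmetric_unit=au, name=name)


def _element_from_label(label: str) -> str:
    sym = "".join(ch for ch in label if ch.isalpha())[:2]
    if len(sym) == 2 and gemmi.Element(sym).atomic_number == 0:
        sym = sym[0]
    return sym.capitalize() if len(sym) == 2 else sym.upper()


def write_cif(crystal: Crystal, path) -> None:
    """Write a crystal as a minimal CIF (cell, symop loop, fractional sites)."""
    frac = cart_to_frac(crystal.lattice, crystal.asymmetric_unit.coords)
    lat = crystal.lattice
    lines = [f"data_{crystal.name.replace(' ', '_')}"]
    for tag, val in zip(_CELL_TAGS, (lat.a, lat.b, lat.c, lat.alpha, lat.beta, lat.gamma)):
        lines.append(f"{tag} {val:.6f}")
    lines.append(f"_symmetry_space_group_name_H-M '{crystal.space_group.symbol}'")
    lines.append("loop_")
    lines.append("_space_group_symop_operation_xyz")
    for op in crystal.space_group.operators:
        gop = gemmi.Op()
        gop.rot = (np.asarray(op.rotation) * gemmi.Op.DEN).tolist()
        gop.tran = np.round(np.asarray(op.translation) * gemmi.Op.DEN).astype(int).tolist()
        lines.append(f"'{gop.triplet()}'")
    lines.append("loop_")
    for t in ("label", "type_symbol", "fract_x", "fract_y", "fract_z"):
        lines.append(f"_atom_site_{t}")
    au = crystal.asymmetric_unit
    for i, (el, f) in enumerate(zip(au.elements, frac)):
        label = au.names[i] if au.names else f"{el}{i + 1}"
        lines.append(f"{label} {el} {f[0]:.9f} {f[1]:.9f} {f[2]:.9f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDB

def read_pdb(path, keep_solvent: bool = False) -> Crystal:
    """Read a macromolecular crystal from a PDB file.

    Requires a CRYST1 record.  Waters and common co-solutes are removed by
    default (``keep_solvent=True`` retains them); each chain becomes one
    molecule of the asymmetric unit.  Alternate locations other than blank
    or 'A' are skipped.
    """
    st = gemmi.read_structure(os.fspath(path), format=gemmi.CoorFormat.Pdb)
    if not st.cell.is_crystal() or st.cell.a <= 0:
        raise ParseError("PDB is missing a CRYST1 record (no unit cell)")
    lattice = LatticeParameters(st.cell.a, st.cell.b, st.cell.c,
                                st.cell.alpha, st.cell.beta, st.cell.gamma)
    symbol = st.spacegroup_hm or "P 1"
    sg = SpaceGroup.from_symbol(symbol)

    elements, coords, names, molecules = [], [], [], []
    model = st[0]
    for chain in model:
        start = len(elements)
        for residue in chain:
            resname = residue.name.strip().upper()
            if not keep_solvent and (resname in SOLVENT_RESIDUES or residue.is_water()):
                continue
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                names.append(atom.name)
        if len(elements) > start:
            molecules.append(np.arange(start, len(elements)))
    if not elements:
        raise ParseError("PDB contains no usable atoms")
    au = AsymmetricUnit(elements=elements, coords=np.array(coords),
                        molecules=molecules, names=names)
    return Crystal(lattice=lattice, space_group=sg, asymmetric_unit=au,
                   name=os.path.splitext(os.path.basename(os.fspath(path)))[0])


def read_crystal(path) -> Crystal:
    """Dispatch on file extension: .cif → CIF, .pdb/.ent → PDB."""
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext == ".cif":
        return read_cif(path)
    if ext in (".pdb", ".ent"):
        return read_pdb(path)
    raise ParseError(f"unrecognized structure format: {ext!r}")


# ---------------------------------------------------------------------------
# Cluster output

def write_cluster(coords_list, elements, path, format: str = "xyz") -> None:
    """Write one or more aligned clusters for visualization.

    ``coords_list`` is a single (n, 3) array or a sequence of them (e.g. the
    two superimposed clusters); multiple clusters become successive XYZ
    frames or PDB MODELs sharing the element list.
    """
    arr = np.asarray(coords_list[0] if isinstance(coords_list, (list, tuple)) else coords_list, dtype=float)
    clusters = [np.asarray(c, dtype=float).reshape(-1, 3) for c in coords_list] \
        if isinstance(coords_list, (list, tuple)) else [arr.reshape(-1, 3)]
    for c in clusters:
        if not np.all(np.isfinite(c)):
            raise ValueError("cluster coordinates must be finite")
        if len(c) != len(elements):
            raise ValueError("coords/elements length mismatch")
    fmt = format.lower()
    if fmt == "xyz":
        lines = []
        for k, c in enumerate(clusters):
            lines.append(str(len(c)))
            lines.append(f"cluster {k + 1}")
            for el, p in zip(elements, c):
                lines.append(f"{el:2s} {p[0]:14.6f} {p[1]:14.6f} {p[2]:14.6f}")
    elif fmt == "pdb":
        lines = []
        for k, c in enumerate(clusters):
            lines.append(f"MODEL     {k + 1:4d}")
            for i, (el, p) in enumerate(zip(elements, c), start=1):
                lines.append(
                    f"HETATM{i:5d} {el.upper():>4s} MOL A   1    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00          {el.upper():>2s}"
                )
            lines.append("ENDMDL")
        lines.append("END")
    else:
        raise ValueError(f"unknown cluster format: {format!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
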