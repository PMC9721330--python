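"""Progressive cluster alignment: the RMSD_N comparison of two crystals.

Given two expanded crystals the comparison proceeds, for each pair of unique
molecular conformations:

1. translate both expansions so the geometric centers of the paired central
   molecules sit at the origin and rotate crystal 2 to superimpose its
   central molecule on crystal 1's (RMSD_1);
2. grow crystal 1's cluster to three molecules under the chosen linkage
   criterion, match those molecules into crystal 2 by geometric-center
   distance, and re-superimpose on the three-molecule atom set (RMSD_3);
3. grow to the full N-molecule cluster, match, and perform the final
   superposition over all selected atoms (RMSD_N), then summarize both final
   clusters with gyration-tensor shape metrics.

The reported RMSD_N is the minimum over all conformer pairs.  Everything is
deterministic: ties break by expansion rank and no randomness enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .expand import (
    DEFAULT_CONFORMER_TOL,
    ExpandedCrystal,
    expand_crystal,
    find_unique_conformers,
    pair_conformers,
)
from .io import AtomSelection, resolve_selection
from .model import Crystal
from .shape import GyrationMetrics, gyration_metrics
from .superpose import quaternion_superpose, rmsd

__all__ = [
    "PacParams",
    "ComparisonResult",
    "linkage_distance",
    "select_cluster",
    "match_by_center",
    "progressive_align_pair",
    "compare_crystals",
]

LINKAGES = ("single", "average", "complete")


@dataclass(frozen=True)
class PacParams:
    """Tunable knobs of a crystal comparison.

    ``n`` is the cluster size in asymmetric units (default 20); ``linkage``
    chooses how molecule-to-cluster distance is measured when growing the
    cluster; ``volume_scalar`` controls how much surplus material the
    expansion provides; ``conformer_tolerance`` is the RMSD_1 below which two
    molecule copies count as one conformation.  ``accretion`` selects whether
    cluster membership is decided by linkage distance to the central molecule
    (the default: the N molecules closest to the central one) or by linkage
    to the growing set (strict hierarchical-clustering semantics, which on
    strongly anisotropic packings degenerates into needle-shaped chains).
    ``conformer_loop=False`` restricts the comparison to the two center-most
    molecules — useful only for diagnostics, since it forfeits enantiomer
    handling in non-Sohncke groups.
    """

    n: int = 20
    linkage: str = "average"
    selection: AtomSelection = field(default_factory=AtomSelection)
    volume_scalar: float = 6.0
    conformer_tolerance: float = DEFAULT_CONFORMER_TOL
    accretion: str = "central"
    conformer_loop: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.accretion not in ("set", "central"):
            raise ValueError("accretion must be 'set' or 'central'")


@dataclass
class ComparisonResult:
    """Outcome of one crystal-vs-crystal comparison."""

    rmsd_n: float
    matched_pairs: list
    cluster_metrics_1: GyrationMetrics
    cluster_metrics_2: GyrationMetrics
    rg_average: float
    winning_conformer_pair: tuple[int, int]
    trace: dict
    params: PacParams | None = None
    cluster_coords_1: np.ndarray | None = None
    cluster_coords_2: np.ndarray | None = None
    cluster_elements: list | None = None


def linkage_distance(coords_a, coords_b, criterion: str) -> float:
    """Distance between two molecules under a linkage criterion (Å).

    single: shortest atom-atom distance; average: distance between the two
    geometric centers; complete: largest atom-atom distance.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty coordinate set")
    if criterion == "average":
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    d = cdist(a, b)
    if criterion == "single":
        return float(d.min())
    if criterion == "complete":
        return float(d.max())
    raise ValueError(f"unknown linkage criterion: {criterion!r}")


def _linkage_to_all(expanded: ExpandedCrystal, index: int, criterion: str) -> np.ndarray:
    """Vectorized linkage distances from one molecule to every molecule."""
    mols = expanded.molecules
    src = mols[index].coords
    if criterion == "average":
        return np.linalg.norm(expanded.centers - src.mean(axis=0), axis=1)
    counts = [len(m.coords) for m in mols]
    stacked = np.concatenate([m.coords for m in mols])
    d = cdist(src, stacked)  # (len(src), total_atoms)
    out = np.empty(len(mols))
    pos = 0
    for i, c in enumerate(counts):
        block = d[:, pos:pos + c]
        out[i] = block.min() if criterion == "single" else block.max()
        pos += c
    return out


def select_cluster(expanded: ExpandedCrystal, center_index: int, n: int,
                   criterion: str = "average", accretion: str = "central") -> list:
    """Choose ``n`` molecules for the cluster, starting from ``center_index``.

    With ``accretion='central'`` (default) the n molecules with the smallest
    linkage distance to the central molecule are taken.  With
    ``accretion='set'`` the cluster grows greedily instead: at each step the
    unselected molecule with the smallest linkage distance to the
    already-selected set joins (set distance = min over members), matching
    hierarchical-clustering semantics.  Ties break by expansion rank.
    Indices come back in selection order, central molecule first.
    """
    m = len(expanded)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > m:
        raise ValueError(
            f"cluster of {n} molecules requested but only {m} expanded; "
            "increase volume_scalar"
        )
    if not 0 <= center_index < m:
        raise IndexError("center_index out of range")
    if n == 1:
        return [center_index]

    # Symmetry-equivalent neighbours are tied at machine precision; snap
    # near-equal distances so that ties reliably break by expansion rank.
    tie = 1e-9

    if accretion == "central":
        d = _linkage_to_all(expanded, center_index, criterion)
        d[center_index] = -1.0  # the seed always comes first
        order = sorted(range(m), key=lambda i: (round(d[i] / tie) * tie, i))
        return order[:n]

    selected = [center_index]
    best = _linkage_to_all(expanded, center_index, criterion)
    best[center_index] = np.inf
    for _ in range(n - 1):
        nxt = int(np.flatnonzero(best <= best.min() + tie)[0])
        selected.append(nxt)
        d = _linkage_to_all(expanded, nxt, criterion)
        best = np.minimum(best, d)
        best[np.asarray(selected)] = np.inf
    return selected


def match_by_center(target_centers, candidate_centers, already_matched=()) -> list:
    """Greedy nearest-center matching of targets into an expansion.

    For each target in order, the unused candidate with the nearest geometric
    center is taken (ties by candidate rank).  Candidates listed in
    ``already_matched`` are excluded from the start.
    """
    targets = np.asarray(target_centers, dtype=float).reshape(-1, 3)
    cands = np.asarray(candidate_centers, dtype=float).reshape(-1, 3)
    used = np.zeros(len(cands), dtype=bool)
    used[list(already_matched)] = True
    if len(targets) > len(cands) - used.sum():
        raise ValueError("candidate pool exhausted: fewer candidates than targets")
    out = []
    for t in targets:
        d = np.linalg.norm(cands - t, axis=1)
        d[used] = np.inf
        j = int(np.argmin(d))
        out.append(j)
        used[j] = True
    return out


def _shifted(expanded: ExpandedCrystal, offset: np.ndarray) -> list:
    return [m.coords + offset for m in expanded.molecules]


def progressive_align_pair(expanded1: ExpandedCrystal, expanded2: ExpandedCrystal,
                           conformer_pair, params: PacParams) -> ComparisonResult:
    """Run the three-stage progressive alignment for one conformer pair.

    ``conformer_pair`` is (index into expansion 1, index into expansion 2)
    naming the central molecules.  The trace records the fit RMSD of each
    stage and, for the two preliminary stages, the unfitted RMSD of the final
    N-molecule cluster under that stage's transform.
    """
    i1, i2 = conformer_pair[0], conformer_pair[1]
    n_mols = params.n * expanded1.source.z_prime

    cluster1 = select_cluster(expanded1, i1, n_mols, params.linkage, params.accretion)
    ref_all = expanded1.coords_of(cluster1) - expanded1.molecules[i1].center
    ref_centers = np.array([expanded1.molecules[k].center for k in cluster1]) \
        - expanded1.molecules[i1].center
    weights1 = expanded1.weights_of(cluster1)
    w_central = expanded1.weights_of([i1])

    # Stage 1: superimpose the central molecules at the origin.
    ref_c = expanded1.molecules[i1].coords - expanded1.molecules[i1].center
    mov_c = expanded2.molecules[i2].coords - expanded2.molecules[i2].center
    fit1 = quaternion_superpose(ref_c, mov_c, w_central)
    origin2 = expanded2.molecules[i2].center
    mov_coords = [fit1.transform(m.coords - origin2) for m in expanded2.molecules]
    mov_centers = np.array([c.mean(axis=0) for c in mov_coords])
    rmsd_1 = fit1.rmsd

    def cluster_rmsd(matches) -> float:
        mov = np.concatenate([mov_coords[j] for j in matches])
        return rmsd(ref_all, mov, weights1)

    # Stage 2: three-molecule alignment.
    triple = cluster1[: min(3, n_mols)]
    matched3 = match_by_center(ref_centers[: len(triple)], mov_centers)
    ref3 = np.concatenate([expanded1.molecules[k].coords - expanded1.molecules[i1].center
                           for k in triple])
    mov3 = np.concatenate([mov_coords[j] for j in matched3])
    w3 = expanded1.weights_of(triple)
    fit2 = quaternion_superpose(ref3, mov3, w3)
    rmsd_3 = fit2.rmsd
    mov_coords = [fit2.transform(c) for c in mov_coords]
    mov_centers = np.array([c.mean(axis=0) for c in mov_coords])

    # Stage 3: full-cluster matching and final fit.
    matched_n = match_by_center(ref_centers, mov_centers)
    mov_all = np.concatenate([mov_coords[j] for j in matched_n])
    fit3 = quaternion_superpose(ref_all, mov_all, weights1)
    rmsd_n = fit3.rmsd
    final2 = fit3.transform(mov_all)
    final1 = ref_all

    # Unfitted RMSD_N of the final cluster under the earlier transforms.
    stage1_mov = np.concatenate(
        [fit1.transform(expanded2.molecules[j].coords - origin2) for j in matched_n])
    trace = {
        "rmsd_1": rmsd_1,
        "rmsd_3": rmsd_3,
        "rmsd_n_stage1": rmsd(ref_all, stage1_mov, weights1),
        "rmsd_n_stage2": cluster_rmsd(matched_n),
        "rmsd_n": rmsd_n,
    }

    g1 = gyration_metrics(final1)
    g2 = gyration_metrics(final2)
    return ComparisonResult(
        rmsd_n=rmsd_n,
        matched_pairs=list(zip(map(int, cluster1), map(int, matched_n))),
        cluster_metrics_1=g1,
        cluster_metrics_2=g2,
        rg_average=0.5 * (g1.rg + g2.rg),
        winning_conformer_pair=(int(i1), int(i2)),
        trace=trace,
        params=params,
        cluster_coords_1=final1,
        cluster_coords_2=final2,
        cluster_elements=expanded1.elements_of(cluster1),
    )


def _validate_chemistry(sel1, sel2) -> None:
    e1 = [tuple(e) for e in sel1.elements]
    e2 = [tuple(e) for e in sel2.elements]
    if set(e1) != set(e2) or len(e1[0]) != len(e2[0]):
        raise ValueError(
            "crystals are not chemically comparable: selected element "
            f"sequences differ ({e1[0][:6]}... vs {e2[0][:6]}...)"
        )


def compare_crystals(crystal1: Crystal, crystal2: Crystal,
                     params: PacParams | None = None) -> ComparisonResult:
    """Full RMSD_N comparison of two crystal descriptions.

    Expands both crystals, identifies and pairs unique molecular
    conformations, runs the progressive alignment for every conformer pair
    and returns the result with the minimal RMSD_N.  The cluster holds
    ``params.n`` asymmetric units of the first crystal; the second crystal
    only needs to describe the same packing, not the same cell (supercell or
    alternative-setting descriptions compare fine).
    """
    params = params or PacParams()
    sel1 = resolve_selection(crystal1, params.selection)
    sel2 = resolve_selection(crystal2, params.selection)
    _validate_chemistry(sel1, sel2)

    n_mols = params.n * crystal1.z_prime
    expanded1 = expand_crystal(crystal1, params.n, sel1, params.volume_scalar)

    if params.conformer_loop:
        reps1 = find_unique_conformers(expanded1, params.conformer_tolerance)
    else:
        reps1 = [0]

    # Crystal 2 must offer a matching candidate for every molecule of crystal
    # 1's cluster.  Linkage accretion can produce elongated clusters (that is
    # what the shape metrics report), so size the second expansion from the
    # realized cluster extent, not just the nominal cluster volume.
    r_cluster = 0.0
    for i1 in reps1:
        cluster = select_cluster(expanded1, i1, n_mols, params.linkage, params.accretion)
        centers = np.array([expanded1.molecules[k].center for k in cluster])
        d = np.linalg.norm(centers - expanded1.molecules[i1].center, axis=1)
        r_cluster = max(r_cluster, float(d.max()))
    cell2 = crystal2.lattice.cell_matrix
    half_diag2 = 0.5 * float(np.linalg.norm(np.abs(cell2).sum(axis=1)))
    n2 = max(1, math.ceil(n_mols / crystal2.z_prime))
    expanded2 = expand_crystal(crystal2, n2, sel2, params.volume_scalar,
                               min_radius=r_cluster + 2.0 * half_diag2 + 2.0)

    if params.conformer_loop:
        reps2 = find_unique_conformers(expanded2, params.conformer_tolerance)
    else:
        reps2 = [0]
    pairs = pair_conformers(expanded1, reps1, expanded2, reps2)

    best: ComparisonResult | None = None
    for i, j, _r1 in pairs:
        result = progressive_align_pair(expanded1, expanded2, (i, j), params)
        if best is None or result.rmsd_n < best.rmsd_n:
            best = result
    assert best is not None
    return best
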