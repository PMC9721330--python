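# Methods

This note documents the model implemented by `pacrys`, the defaults that
matter, the numerical choices, and what the synthetic test crystals do and
do not establish about real data.

## Problem and representation

Two descriptions of a molecular crystal — space group, lattice parameters,
asymmetric-unit coordinates — are compared by superimposing finite clusters
of N whole molecules drawn from each infinite packing and reporting the
coordinate RMSD over the cluster (RMSD_N), together with shape descriptors
of the compared clusters.  The measure is invariant to the crystallographic
bookkeeping: origin choice, cell setting and supercell descriptions of the
same packing all compare at RMSD_N ≈ 0.

Internally a crystal is Cartesian: fractional coordinates are mapped through
the conventional cell matrix (a along x, b in the x–y plane).  The
convention is arbitrary — all comparisons happen in Cartesian space — but
fixed, so fractional/Cartesian round trips are exact to 1e-12.  Space-group
operators come from the input file when a CIF symmetry loop is present
(files are authoritative); otherwise they are resolved by Hermann–Mauguin
symbol or IT number from gemmi's tables, with centering translations
expanded into the explicit operator list.

Atom correspondence between the two crystals is positional: the selected
atoms of each molecule must appear in the same order with the same element
sequence, which is validated and fails loudly otherwise.  No graph/label
canonicalization is attempted.

## Expansion (step 1)

Each asymmetric-unit molecule is transformed rigidly by every operator and
its *center* wrapped into the home cell by whole lattice translations —
molecules are never split across cell boundaries.  The home cell is then
replicated over a centered block of lattice translations.  The block is
sized two ways and the larger wins:

* **molecule budget** — at least `volume_scalar × N × Z'` molecules
  (default scalar 6).  Because whole cells are replicated, molecule count is
  an exact proxy for occupied volume;
* **geometric cover** — the block must cover a sphere of
  `volume_scalar` × (expected cluster volume) plus a one-cell margin around
  its center, where the expected cluster volume is `V_cell / molecules-per-
  cell × N`.  Interplanar spacings of the three axis directions decide how
  many cells each axis needs, so skewed and elongated cells still produce a
  roughly isometric block.

The second rule exists because a count-only block can be lopsided: a
re-expressed description (shifted origin, supercell) centers its block
elsewhere, and cluster molecules near the block boundary would have no
matching candidate, turning an exact equivalence into a multi-Å artifact.
Additionally, when two crystals are compared, the second crystal's block is
grown to cover the *realized* extent of the first crystal's selected cluster
(plus two cell diagonals), since linkage selection can legitimately produce
elongated clusters that outrun any volume-based estimate.

Molecules are ranked by the distance of their geometric center from the
grand center of all expanded atoms; ties (symmetry-equivalent shells) break
lexicographically by (operator, lattice shift, source molecule), so the
ordering is deterministic.

## Unique conformations and pairing (step 2)

Walking the ranked molecules, a molecule starts a new conformation when its
best proper-rotation RMSD₁ against every existing representative exceeds a
tolerance (default 0.1 Å, configurable).  Only proper rotations are used, so
in an enantiogenic group the two hands of a chiral molecule count as two
conformations; for rigid molecules the count is bounded by Z' (Sohncke) or
2 Z' (otherwise), and the scan stops at the bound.  Representatives of the
two crystals are paired all-against-all and processed in ascending RMSD₁
order; the final result is the minimum RMSD_N over the pairs.  This loop is
what matches a crystal against an enantiomorphic description of itself; the
`conformer_loop=False` diagnostic switch disables it and demonstrably
degrades exactly those comparisons.

## Progressive alignment (step 3)

For one conformer pair (the central molecules): both expansions are
translated so the central molecules' geometric centers sit at the origin and
the second crystal is rotated to superimpose its central molecule on the
first's (RMSD₁).  The first crystal's cluster is grown to three molecules
under the linkage criterion; each is matched to the unused second-crystal
molecule with the nearest geometric center (in the current frame, after the
stage-1 rotation), and the superposition is repeated over the three-molecule
atom set (RMSD₃).  Finally the full N-molecule cluster is selected, matched
the same way, and the last superposition over all selected atoms gives
RMSD_N.  One pass is performed per conformer pair; no iteration if second-
crystal selections would shift mid-alignment.  The trace also records the
unfitted RMSD of the final cluster under the stage-1 and stage-2 transforms,
which shows the progressive improvement and upper-bounds the final value.

All superpositions are quaternion-based: the minimal weighted squared
deviation is the smallest eigenvalue of the symmetric 4×4 Kearsley matrix
of the centered coordinate sums, and its eigenvector is the rotation
quaternion.  Improper rotations are never produced; the explicit mirror
branch (`superpose_mirror_allowed`) exists only for conformer analysis.
The reported RMSD is recomputed from the rotated coordinates rather than as
√λ_min, which loses half the significant digits near an exact fit.  With
degenerate eigenvalues (symmetric point sets) the RMSD is still unique and
the eigensolver's deterministic eigenvector fixes the rotation.

### Cluster selection semantics

The three linkage criteria are single (minimum atom–atom distance), average
(geometric-center distance) and complete (maximum atom–atom distance).  Two
selection semantics are implemented:

* `accretion="central"` (default): the N molecules with the smallest
  linkage distance *to the central molecule*.
* `accretion="set"`: hierarchical-clustering accretion — repeatedly add the
  molecule with the smallest linkage distance to the growing set.

The default is central.  Strict set-accretion degenerates on anisotropic
packings: whenever one contact direction is strictly shortest, the greedy
set minimum stays in that direction forever and the "cluster" becomes a
1-D needle (observed: 20-molecule clusters nearly 50 Å long), which defeats
the purpose of a packing shell and produces R_g values far outside the
range a 20-molecule shell should have.  Distance-to-central selection keeps
clusters shell-like while still letting the criterion shape them — single
linkage favors tight-contact directions (more elongated, higher R_g),
average linkage weights all directions by center distance (more spherical).
Near-tied linkage distances (symmetry-equivalent shells, equal to ~1e-15
but computed through different floating-point paths) are snapped at 1e-9 Å
so that ties break by expansion rank, making selection deterministic and
independent of vectorization details.

With Z' > 1, one "comparison unit" is an asymmetric unit: N means N × Z'
molecules, all selected and matched individually.  When the two descriptions
have different Z' (e.g. crystal vs its P1 supercell), the cluster size in
molecules is N × Z' of the *first* crystal; the second crystal only
contributes candidates.  When unit-cell volumes genuinely differ, scaling N
by the volume ratio (e.g. N=40 against a doubled cell) keeps the compared
material equivalent.

## Shape metrics

The gyration tensor is S_ij = (1/N) Σ_k (r_k − GC)_i (r_k − GC)_j over the
cluster's selected atoms, GC the unweighted geometric center.  The 1/N
normalization makes the trace identity R_g² = λ_min + λ_med + λ_max hold
with the conventional radius of gyration; an unnormalized tensor is
available (`normalize=False`) for readers who prefer the raw sum.  The
auxiliary descriptors use the standard polymer-physics definitions:
asphericity b = λ_max − (λ_med + λ_min)/2, acylindricity c = λ_med − λ_min,
relative shape anisotropy κ² = (b² + ¾c²)/(Σλ)², with the closed-form
limits κ² = 0 (sphere), 1 (rod), ¼ (disc), and all three defined as 0 for a
degenerate zero-moment cluster.  R_g is reported per cluster and as the
average over the two compared clusters.  Moments of inertia are the only
mass-weighted quantity (true atomic masses, about the center of mass);
everything else is geometric unless mass weighting is requested, to avoid
over-prioritizing heavy elements.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| `n` | 20 | cluster size in asymmetric units |
| `linkage` | average | molecule-distance criterion for cluster growth |
| `selection.mode` | heavy | atoms compared (H/D excluded); `alpha_carbon`, `all`, `custom` |
| `selection.mass_weighted` | False | unit weights; masses on request |
| `volume_scalar` | 6 | expansion volume multiple |
| `conformer_tolerance` | 0.1 Å | RMSD₁ below which two copies are one conformation |
| `accretion` | central | cluster-selection semantics (see above) |

## Synthetic crystals

All tests and the acceptance script run on crystals built by
`pacrys.fixtures`: four rigid toy molecules (an elongated zigzag rod, a bent
planar frame, a chiral tetrahedral center with four distinct arms, a
strictly planar achiral frame, plus an acetamide-like molecule with
hydrogens for selection tests) placed with seeded random orientation and
position into P1, P-1, P2₁, P2₁/c or P2₁2₁2₁ cells, retrying until all
intermolecular contacts in a 3×3×3 block exceed 1.5 Å.  The rod is a slight
zigzag rather than a straight line because a perfectly collinear molecule
leaves the single-molecule superposition rotation under-determined (free
spin about the axis) — a degeneracy no real elongated molecule has;
collinear *point sets* are still exercised in the superposition oracle
tests.  Perturbed copies add seeded i.i.d. Gaussian coordinate noise (the
same seed draws the same unit noise, so different σ are directly
comparable) and/or scale the cell edges; re-expressed copies shift the
origin by a symmetry-allowed vector, change the lattice basis (a′ = a + c,
operators conjugated and verified integer), or rewrite the crystal as an
explicit P1 2×1×1 supercell.

What the fixtures emulate: rigid-molecule polymorph comparison, experimental
vs minimized/strained lattices, enantiogenic packing, description
degeneracy.  What they do not: molecular flexibility (every copy is exactly
rigid, so the conformer count bounds are sharp), disorder and partial
occupancy, special positions, polymeric/covalent networks, realistic
packing densities or energies, and atom-order mismatches between inputs.
Passing tests therefore demonstrate the algorithm's correctness and
invariances, not robustness to conformational noise beyond the Gaussian
perturbations tested.

## Determinism, degenerate inputs, limitations

No randomness enters the comparison pipeline; all ties break by expansion
rank, and repeated runs (and any worker count in the batch driver, which
partitions the pair list into contiguous blocks per process) produce
byte-identical results.  Single-point and collinear superposition inputs are
legal (RMSD is unique; the rotation is whatever the degenerate eigenproblem
yields).  Comparisons of chemically different crystals, empty selections,
exhausted candidate pools and degenerate lattices raise descriptive errors.

Known limitations: molecules are assumed whole within one asymmetric unit
and identical in atom order across inputs; only a fallback subset of
space-group settings has been exercised (any group parses if its operators
are listed in the CIF); cluster-size scaling for volume-mismatched
comparisons is the caller's responsibility; and RMSD_N grows with N under
lattice mismatch by construction, so N must match when comparing numbers
across studies.

## Problem sizes used in tests

The suite runs self- and cross-comparisons at N = 20 (up to 80 for the
cluster-size scaling check), expansions of a few hundred to a few thousand
molecules, a 16-crystal all-vs-all batch (136 pairs, 1 vs 4 workers), and
200-pair superposition-oracle sweeps — sizes chosen so the whole suite
completes in about two minutes on one CPU while still exercising every
code path at the method's default cluster size.
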