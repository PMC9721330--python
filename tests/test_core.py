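import math
from dataclasses import replace

import numpy as np
import pytest

from pacrys import (
    PacParams,
    compare_crystals,
    expand_crystal,
    linkage_distance,
    match_by_center,
    progressive_align_pair,
    select_cluster,
)
from pacrys.expand import find_unique_conformers, pair_conformers
from pacrys.fixtures import FixtureSpec, make_crystal, perturb_crystal, reexpress_crystal


class TestLinkageDistance:
    def test_two_rods_hand_geometry(self):
        a = [[0, 0, 0], [1, 0, 0]]
        b = [[3, 0, 0], [4, 0, 0]]
        assert linkage_distance(a, b, "single") == pytest.approx(2.0)
        assert linkage_distance(a, b, "average") == pytest.approx(3.0)
        assert linkage_distance(a, b, "complete") == pytest.approx(4.0)

    def test_identical_molecules_zero_single(self, rng):
        pts = rng.normal(size=(6, 3))
        assert linkage_distance(pts, pts, "single") == 0.0

    def test_against_brute_force_oracle(self, rng):
        for _ in range(30):
            a = rng.normal(size=(int(rng.integers(2, 8)), 3)) * 3
            b = rng.normal(size=(int(rng.integers(2, 8)), 3)) * 3 + 5
            all_d = [np.linalg.norm(p - q) for p in a for q in b]
            assert linkage_distance(a, b, "single") == pytest.approx(min(all_d))
            assert linkage_distance(a, b, "complete") == pytest.approx(max(all_d))
            assert linkage_distance(a, b, "average") == pytest.approx(
                np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
            assert linkage_distance(a, b, "single") <= linkage_distance(a, b, "complete")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            linkage_distance(np.empty((0, 3)), np.zeros((2, 3)), "single")


def greedy_oracle(expanded, center, n, criterion, accretion):
    """Brute-force re-derivation of cluster selection, recomputing every
    linkage distance at every step."""
    from pacrys import linkage_distance as ld
    mols = expanded.molecules
    snap = lambda x: round(x / 1e-9) * 1e-9  # near-ties break by rank
    if accretion == "central":
        d = [(snap(ld(mols[center].coords, m.coords, criterion)), i)
             for i, m in enumerate(mols) if i != center]
        d.sort(key=lambda t: (t[0], t[1]))
        return [center] + [i for _d, i in d[: n - 1]]
    selected = [center]
    while len(selected) < n:
        best, best_i = math.inf, None
        for i in range(len(mols)):
            if i in selected:
                continue
            dist = min(ld(mols[s].coords, mols[i].coords, criterion) for s in selected)
            if dist < best - 1e-9:
                best, best_i = dist, i
        selected.append(best_i)
    return selected


class TestSelectCluster:
    def test_n1_returns_center(self, p21_crystal):
        e = expand_crystal(p21_crystal, 5)
        assert select_cluster(e, 3, 1) == [3]

    def test_equals_greedy_oracle(self, p21_crystal):
        e = expand_crystal(p21_crystal, 6)
        for criterion in ("single", "average", "complete"):
            for accretion in ("central", "set"):
                got = select_cluster(e, 0, 6, criterion, accretion)
                assert got == greedy_oracle(e, 0, 6, criterion, accretion)

    def test_insufficient_molecules_message(self, p21_crystal):
        e = expand_crystal(p21_crystal, 2, volume_scalar=1)
        with pytest.raises(ValueError, match="volume_scalar"):
            select_cluster(e, 0, len(e) + 1)

    def test_chain_single_linkage_picks_adjacent(self, rod_crystal):
        """With tight end-to-end stacking, single linkage takes the two
        molecules sharing the shortest atomic contacts with the center."""
        e = expand_crystal(rod_crystal, 5)
        cl = select_cluster(e, 0, 3, "single")
        centers = np.array([e.molecules[i].center for i in cl])
        d = np.linalg.norm(centers[1:] - centers[0], axis=1)
        # nearest neighbours along the stacking axis, one cell apart
        assert np.all(d < 1.05 * rod_crystal.lattice.a)


class TestMatchByCenter:
    def test_exact_candidates(self, rng):
        pts = rng.normal(size=(8, 3)) * 5
        assert match_by_center(pts, pts) == list(range(8))

    def test_nearer_candidate_wins(self):
        assert match_by_center([[0, 0, 0]], [[2, 0, 0], [1, 0, 0]]) == [1]

    def test_without_replacement_matches_exhaustive_oracle(self, rng):
        targets = rng.normal(size=(10, 3)) * 4
        cands = rng.normal(size=(40, 3)) * 4
        got = match_by_center(targets, cands)
        used = set()
        expected = []
        for t in targets:
            d = np.linalg.norm(cands - t, axis=1)
            order = np.argsort(d, kind="stable")
            pick = next(int(i) for i in order if int(i) not in used)
            used.add(pick)
            expected.append(pick)
        assert got == expected
        assert len(set(got)) == len(got)

    def test_pool_exhaustion(self):
        with pytest.raises(ValueError):
            match_by_center(np.zeros((3, 3)), np.zeros((2, 3)))


class TestProgressiveAlignment:
    def test_self_comparison_trace_is_zero(self, p21_crystal):
        e = expand_crystal(p21_crystal, 10)
        result = progressive_align_pair(e, e, (0, 0), PacParams(n=10))
        assert result.rmsd_n < 1e-6
        assert result.trace["rmsd_1"] < 1e-6
        assert result.trace["rmsd_3"] < 1e-6
        assert len(result.matched_pairs) == 10

    def test_noise_final_not_worse_than_first_stage(self, p21_crystal):
        """For a mildly noised copy the final fitted RMSD_N cannot exceed the
        unfitted cluster RMSD after the single-molecule alignment."""
        noisy = perturb_crystal(p21_crystal, 0.05, 1.0, seed=21)
        result = compare_crystals(p21_crystal, noisy, PacParams(n=20))
        assert result.rmsd_n > 0
        assert result.rmsd_n <= result.trace["rmsd_n_stage1"] + 1e-12
        assert result.rmsd_n <= result.trace["rmsd_n_stage2"] + 1e-12


class TestCompareCrystals:
    @pytest.mark.parametrize("group", ["P 1", "P -1", "P 21", "P 21/c", "P 21 21 21"])
    def test_identity(self, bent_crystals, group):
        result = compare_crystals(bent_crystals[group], bent_crystals[group], PacParams(n=20))
        assert result.rmsd_n < 1e-6
        assert result.trace["rmsd_1"] < 1e-6
        assert result.trace["rmsd_3"] < 1e-6

    def test_identity_z_prime_2(self, z2_crystal):
        params = PacParams(n=10)
        result = compare_crystals(z2_crystal, z2_crystal, params)
        assert result.rmsd_n < 1e-6
        assert len(result.matched_pairs) == 10 * 2  # n asymmetric units, Z'=2

    def test_rotated_setting_equivalence(self, p21_crystal):
        other = reexpress_crystal(p21_crystal, "rotated_setting")
        assert compare_crystals(p21_crystal, other, PacParams(n=20)).rmsd_n < 1e-3

    def test_minimum_over_conformer_pairs(self, chiral_p21c_crystal):
        """The reported RMSD_N is the minimum over every conformer pairing."""
        crystal = chiral_p21c_crystal
        params = PacParams(n=8)
        e1 = expand_crystal(crystal, 8)
        reps = find_unique_conformers(e1)
        assert len(reps) == 2
        pairs = pair_conformers(e1, reps, e1, reps)
        per_pair = [progressive_align_pair(e1, e1, (i, j), params).rmsd_n
                    for i, j, _r in pairs]
        result = compare_crystals(crystal, crystal, params)
        assert result.rmsd_n <= min(per_pair) + 1e-12

    def test_deterministic_repeat(self, p21_crystal):
        noisy = perturb_crystal(p21_crystal, 0.03, 1.0, seed=5)
        a = compare_crystals(p21_crystal, noisy, PacParams(n=12))
        b = compare_crystals(p21_crystal, noisy, PacParams(n=12))
        assert a.rmsd_n == b.rmsd_n
        assert a.matched_pairs == b.matched_pairs
        assert a.cluster_coords_2.tobytes() == b.cluster_coords_2.tobytes()

    def test_element_mismatch_rejected(self, p21_crystal):
        other = make_crystal(FixtureSpec(molecule_shape="rod", space_group="P 21", seed=1))
        with pytest.raises(ValueError, match="element"):
            compare_crystals(p21_crystal, other)

    def test_trace_identity_of_shape_metrics(self, p21_crystal):
        result = compare_crystals(p21_crystal, p21_crystal, PacParams(n=15))
        for g in (result.cluster_metrics_1, result.cluster_metrics_2):
            assert g.rg**2 == pytest.approx(sum(g.moments), abs=1e-10)


class TestPacParamsValidation:
    def test_bad_linkage(self):
        with pytest.raises(ValueError):
            PacParams(linkage="ward")

    def test_bad_n(self):
        with pytest.raises(ValueError):
            PacParams(n=0)
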