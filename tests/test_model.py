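import numpy as np
import pytest

from pacrys import (
    Crystal,
    InvalidLatticeError,
    LatticeParameters,
    SpaceGroup,
    SymmetryOperator,
    cart_to_frac,
    expected_cluster_volume,
    frac_to_cart,
    unit_cell_volume,
)
from pacrys.model import atomic_mass, covalent_radius


class TestLatticeParameters:
    def test_rejects_nonpositive_edges_and_bad_angles(self):
        with pytest.raises(InvalidLatticeError):
            LatticeParameters(-1, 5, 5)
        with pytest.raises(InvalidLatticeError):
            LatticeParameters(5, 5, 5, alpha=0)
        with pytest.raises(InvalidLatticeError):
            LatticeParameters(5, 5, 5, gamma=180)

    def test_rejects_degenerate_cell(self):
        # impossible angle combination -> negative metric radicand
        with pytest.raises(InvalidLatticeError):
            LatticeParameters(5, 5, 5, 10, 10, 170)


class TestVolume:
    @pytest.mark.parametrize(
        "lat,expected",
        [
            (LatticeParameters(10, 10, 10), 1000.0),
            (LatticeParameters(10, 20, 30), 6000.0),
        ],
    )
    def test_orthogonal_cells(self, lat, expected):
        assert unit_cell_volume(lat) == pytest.approx(expected, rel=1e-12)

    def test_triclinic_volume_equals_cell_matrix_determinant(self):
        lat = LatticeParameters(5.4, 6.1, 7.3, 91, 103, 119)
        det = abs(np.linalg.det(lat.cell_matrix))
        assert unit_cell_volume(lat) == pytest.approx(det, rel=1e-12)

    def test_volume_matches_determinant_for_random_lattices(self, rng):
        n_ok = 0
        while n_ok < 1000:
            a, b, c = rng.uniform(3, 30, 3)
            al, be, ga = rng.uniform(50, 130, 3)
            try:
                lat = LatticeParameters(a, b, c, al, be, ga)
            except InvalidLatticeError:
                continue
            n_ok += 1
            assert unit_cell_volume(lat) == pytest.approx(
                abs(np.linalg.det(lat.cell_matrix)), rel=1e-9)


class TestFracCart:
    def test_cubic_midpoint(self):
        lat = LatticeParameters(10, 10, 10)
        assert np.allclose(frac_to_cart(lat, [0.5, 0.5, 0.5]), [5, 5, 5])

    def test_origin_is_fixed_point(self):
        lat = LatticeParameters(5.4, 6.1, 7.3, 91, 103, 119)
        assert np.allclose(frac_to_cart(lat, [0, 0, 0]), [0, 0, 0])

    def test_a_axis_along_x_b_in_xy_plane(self):
        lat = LatticeParameters(5.4, 6.1, 7.3, 91, 103, 119)
        M = lat.cell_matrix
        assert M[1, 0] == M[2, 0] == 0.0
        assert M[2, 1] == 0.0

    def test_round_trip_triclinic(self, rng):
        lat = LatticeParameters(5.4, 6.1, 7.3, 91, 103, 119)
        v = rng.uniform(-3, 3, size=(100, 3))
        back = cart_to_frac(lat, frac_to_cart(lat, v))
        assert np.abs(back - v).max() < 1e-10


class TestSymmetryOperator:
    def test_rejects_non_unimodular_rotation(self):
        with pytest.raises(ValueError):
            SymmetryOperator(np.diag([2, 1, 1]), np.zeros(3))

    def test_screw_axis_from_triplet(self):
        op = SymmetryOperator.from_xyz("-x, y+1/2, -z")
        assert np.array_equal(op.rotation, np.diag([-1, 1, -1]))
        assert np.allclose(op.translation, [0, 0.5, 0])
        assert op.is_proper

    def test_translation_wrapped_to_unit_interval(self):
        op = SymmetryOperator(np.eye(3), [1.25, -0.25, 0.0])
        assert np.allclose(op.translation, [0.25, 0.75, 0.0])

    def test_rigid_motion_in_cartesian_space(self, rng):
        """Operators must preserve interatomic distances when mapped through
        the cell."""
        lat = LatticeParameters(9.5, 10.5, 9.0, 90, 101, 90)
        op = SymmetryOperator.from_xyz("-x, y+1/2, -z")
        pts = rng.uniform(0, 5, size=(8, 3))
        frac = cart_to_frac(lat, pts)
        moved = frac_to_cart(lat, op.apply(frac))
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9


class TestSpaceGroup:
    @pytest.mark.parametrize(
        "symbol,order,sohncke",
        [
            ("P 1", 1, True),
            ("P -1", 2, False),
            ("P 21", 2, True),
            ("P 21/c", 4, False),
            ("P 21 21 21", 4, True),
            ("C 2/c", 8, False),
            ("Pbca", 8, False),
            ("Pccn", 8, False),
            ("P 21/n", 4, False),
        ],
    )
    def test_order_and_sohncke_flag(self, symbol, order, sohncke):
        sg = SpaceGroup.from_symbol(symbol)
        assert sg.order == order
        assert sg.is_sohncke is sohncke

    def test_group_closure_on_small_groups(self):
        for symbol in ("P 21", "P 21/c", "P 21 21 21"):
            sg = SpaceGroup.from_symbol(symbol)
            ops = sg.operators
            for a in ops:
                for b in ops:
                    rot = a.rotation @ b.rotation
                    tran = a.rotation @ b.translation + a.translation
                    prod = SymmetryOperator(rot, tran)
                    assert any(prod == c for c in ops)

    def test_identity_required(self):
        with pytest.raises(ValueError):
            SpaceGroup(number=0, symbol="?", operators=[
                SymmetryOperator(np.diag([-1, -1, -1]), np.zeros(3))])

    def test_unknown_symbol(self):
        with pytest.raises(ValueError):
            SpaceGroup.from_symbol("Q 99")


class TestExpectedClusterVolume:
    def test_forced_arithmetic(self, bent_crystals):
        c = bent_crystals["P 21 21 21"]  # 4 operators, Z'=1
        v = unit_cell_volume(c.lattice)
        assert expected_cluster_volume(c, 20) == pytest.approx(v / 4 * 20)

    def test_p1_single_molecule(self, bent_crystals):
        c = bent_crystals["P 1"]
        assert expected_cluster_volume(c, 1) == pytest.approx(
            unit_cell_volume(c.lattice))

    def test_molecule_count_by_explicit_symmetry(self, z2_crystal):
        # P 21, Z'=2: 4 molecules per cell counted by operators x Z'
        assert z2_crystal.molecules_per_cell == 4
        v = unit_cell_volume(z2_crystal.lattice)
        assert expected_cluster_volume(z2_crystal, 20) == pytest.approx(v / 4 * 20)

    def test_rejects_nonpositive_n(self, bent_crystals):
        with pytest.raises(ValueError):
            expected_cluster_volume(bent_crystals["P 1"], 0)


def test_element_data_lookup():
    assert atomic_mass("C") == pytest.approx(12.011, abs=0.01)
    assert covalent_radius("H") < covalent_radius("S")
    with pytest.raises(ValueError):
        atomic_mass("Xq")


def test_crystal_rejects_far_out_coordinates(bent_crystals):
    c = bent_crystals["P 1"]
    au = c.asymmetric_unit
    from pacrys import AsymmetricUnit
    with pytest.raises(ValueError):
        Crystal(lattice=c.lattice, space_group=c.space_group,
                asymmetric_unit=AsymmetricUnit(
                    elements=list(au.elements), coords=au.coords + 500.0,
                    molecules=[m.copy() for m in au.molecules]))
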