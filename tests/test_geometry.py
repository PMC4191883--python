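"""Geometric descriptors: CoM, distances, tilt, Kabsch, gates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statemap.structio import SelectionSpec
from statemap.geometry import (SegmentDef, GateDef, center_of_mass,
                               com_distance, helix_axis, tilt_angle,
                               kabsch_rmsd, gate_distance, gate_is_closed)
from statemap.synthgen import make_ideal_helix
from conftest import pseudo_model, random_rotation


def _seg(name, first, last, atoms=("CA",)):
    return SegmentDef(name, SelectionSpec(first=first, last=last,
                                          atom_names=frozenset(atoms)))


class TestCenterOfMass:
    def test_single_atom(self):
        m = pseudo_model([[1.0, 2.0, 3.0]])
        assert np.allclose(center_of_mass(m, [0]), [1, 2, 3])

    def test_two_equal_atoms(self):
        m = pseudo_model([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(center_of_mass(m, [0, 1]), [1, 0, 0])

    def test_mass_weighting_matches_direct_sum(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-10, 10, (20, 3))
        elements = rng.choice(["C", "N", "O", "S"], 20)
        m = pseudo_model(coords)
        m.element = elements
        m.masses = None
        com = center_of_mass(m, np.arange(20), "mass")
        w = m.get_masses()
        expected = np.zeros(3)
        for i in range(20):  # explicit loop oracle
            expected += w[i] * coords[i]
        expected /= w.sum()
        assert np.allclose(com, expected, atol=1e-12)

    def test_empty_selection_errors(self):
        m = pseudo_model([[0, 0, 0]])
        with pytest.raises(ValueError):
            center_of_mass(m, [])


class TestComDistance:
    def test_two_single_atom_segments(self):
        m = pseudo_model([[0, 0, 0], [0, 3, 4]], atom_name="CA")
        a = _seg("A", 1, 1)
        b = _seg("B", 2, 2)
        assert com_distance(m, a, b) == pytest.approx(5.0)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        m = pseudo_model(rng.uniform(-5, 5, (10, 3)), atom_name="CA")
        a, b = _seg("A", 1, 5), _seg("B", 6, 10)
        assert com_distance(m, a, b) == pytest.approx(
            com_distance(m, b, a))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-10, 10, (12, 3))
        m1 = pseudo_model(coords, atom_name="CA")
        rot = random_rotation(rng)
        m2 = pseudo_model(coords @ rot.T + rng.uniform(-20, 20, 3),
                          atom_name="CA")
        a, b = _seg("A", 1, 6), _seg("B", 7, 12)
        assert com_distance(m1, a, b) == pytest.approx(
            com_distance(m2, a, b), abs=1e-9)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(7)
        m = pseudo_model(rng.uniform(-10, 10, (9, 3)), atom_name="CA")
        a, b, c = _seg("A", 1, 3), _seg("B", 4, 6), _seg("C", 7, 9)
        ab = com_distance(m, a, b)
        bc = com_distance(m, b, c)
        ac = com_distance(m, a, c)
        assert ac <= ab + bc + 1e-12


class TestHelixAxisAndTilt:
    def test_ideal_helix_axis_along_z(self):
        # ~5 full turns so the Cα cloud is rotationally balanced
        xyz = make_ideal_helix(20)
        axis = helix_axis(xyz)
        assert axis @ np.array([0, 0, 1.0]) > 0.999

    def test_rotated_helix_axis_recovered(self):
        xyz = make_ideal_helix(15)
        ang = np.deg2rad(30)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        axis = helix_axis(xyz @ rot.T)
        expected = rot @ helix_axis(xyz)
        assert np.degrees(np.arccos(np.clip(axis @ expected, -1, 1))) < 1.0

    def test_too_few_atoms_errors(self):
        with pytest.raises(ValueError):
            helix_axis(np.array([[0, 0, 0], [1, 0, 0]]))

    @pytest.mark.parametrize("axis,ref,expected", [
        ((0, 0, 1), (0, 0, 1), 0.0),
        ((1 / np.sqrt(2), 0, 1 / np.sqrt(2)), (0, 0, 1), 45.0),
        ((1, 0, 0), (0, 0, 1), 90.0),
    ])
    def test_tilt_values(self, axis, ref, expected):
        assert tilt_angle(axis, ref) == pytest.approx(expected, abs=1e-9)

    def test_tilt_zero_norm_errors(self):
        with pytest.raises(ValueError):
            tilt_angle((0, 0, 0), (0, 0, 1))

    def test_known_rotation_changes_tilt_by_that_angle(self):
        """A 40° rotation of the helix changes its tilt by 40° ± 1°."""
        xyz = make_ideal_helix(12)
        t0 = tilt_angle(helix_axis(xyz))
        ang = np.deg2rad(40)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        t1 = tilt_angle(helix_axis(xyz @ rot.T))
        assert t1 - t0 == pytest.approx(40.0, abs=1.0)


def _quaternion_rmsd(a, b):
    """Independent superposition oracle (Horn's quaternion method)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    e = (np.sum(a ** 2) + np.sum(b ** 2) - 2 * lam) / a.shape[0]
    return np.sqrt(max(e, 0.0))


class TestKabsch:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-5, 5, (8, 3))
        rmsd, _, _ = kabsch_rmsd(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rotated_translated_copy_zero(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-5, 5, (8, 3))
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        b = a @ rot.T + np.array([3.0, -2.0, 7.0])
        rmsd, r, t = kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(b @ r.T + t, a, atol=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, (5, 3))
        b = rng.uniform(-5, 5, (5, 3))
        rmsd, _, _ = kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(_quaternion_rmsd(a, b), abs=1e-6)

    def test_mismatched_counts_error(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-5, 5, (6, 3))
        b = rng.uniform(-5, 5, (6, 3))
        assert kabsch_rmsd(a, b)[0] == pytest.approx(
            kabsch_rmsd(b, a)[0], abs=1e-9)


class TestGates:
    def _gate(self, cutoff=4.0, kind="salt_bridge"):
        return GateDef(
            "test", SelectionSpec(1, 1, frozenset({"N"})),
            SelectionSpec(2, 2, frozenset({"O"})), cutoff, kind)

    def test_min_cross_pair(self):
        m = pseudo_model([[0, 0, 0], [3, 0, 0], [4, 0, 0]])
        m.atom_name = np.array(["N", "O", "O"])
        m.res_id = np.array([1, 2, 2])
        assert gate_distance(m, self._gate()) == pytest.approx(3.0)

    def test_swap_partners_symmetric(self):
        m = pseudo_model([[0, 0, 0], [3, 0, 0]])
        m.atom_name = np.array(["N", "O"])
        m.res_id = np.array([1, 2])
        g = self._gate()
        g2 = GateDef("swap", g.sel_b, g.sel_a, g.cutoff, g.kind)
        assert gate_distance(m, g) == pytest.approx(gate_distance(m, g2))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        pa = rng.uniform(-8, 8, (6, 3))
        pb = rng.uniform(-8, 8, (9, 3))
        coords = np.vstack([pa, pb])
        m = pseudo_model(coords)
        m.atom_name = np.array(["N"] * 6 + ["O"] * 9)
        m.res_id = np.array([1] * 6 + [2] * 9)
        expected = min(np.linalg.norm(x - y) for x in pa for y in pb)
        assert gate_distance(m, self._gate()) == pytest.approx(expected)

    def test_missing_sidechain_atoms_named_in_error(self):
        m = pseudo_model([[0, 0, 0]])
        m.atom_name = np.array(["N"])
        with pytest.raises(ValueError, match="test"):
            gate_distance(m, self._gate())

    @pytest.mark.parametrize("dist,closed", [
        (3.2, True), (4.0, True), (12.0, False)])
    def test_closed_convention(self, dist, closed):
        assert gate_is_closed(dist, self._gate()) is closed
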