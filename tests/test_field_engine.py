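"""Grid construction, probe-energy and similarity-index fields, pretreatment."""

import math

import numpy as np
import pytest

import fieldqsar as fq
from fieldqsar.errors import DegenerateInputError, DomainError, ValidationError
from fieldqsar.field_engine import (
    COULOMB_CONSTANT,
    LJ_PARAMS,
    comfa_values_at_points,
    comsia_values_at_points,
)
from fieldqsar.molecule import FLAG_KEYS, Molecule3D


def _atom(element="C", pos=(0, 0, 0), charge=0.0, **flagnames):
    flags = {k: np.array([flagnames.get(k, False)]) for k in FLAG_KEYS}
    return Molecule3D(id="a", elements=[element], coords=np.array([pos], float),
                      charges=np.array([charge]), flags=flags,
                      formal_charge=charge)


class TestBuildGrid:
    def test_single_atom_margin(self):
        grid = fq.build_grid([_atom()], spacing=2.0, margin=4.0)
        assert grid.dimensions == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_zero_margin_single_atom(self):
        grid = fq.build_grid([_atom()], spacing=2.0, margin=0.0)
        assert grid.dimensions == (1, 1, 1)
        assert grid.origin == (0.0, 0.0, 0.0)

    def test_library_contained(self, small_library):
        grid = fq.build_grid(small_library.molecules, 2.0, 4.0)
        for m in small_library.molecules:
            assert grid.contains(m.coords)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            fq.build_grid([], 2.0, 4.0)


class TestComfa:
    def test_coulomb_hand_value_clamped(self):
        """A +1 e probe 1 Å from a +1 e atom with eps(r)=r sees 332.0636
        kcal/mol, clamped to +30."""
        mol = _atom(charge=1.0)
        pts = np.array([[1.0, 0.0, 0.0]])
        _, ele, _ = comfa_values_at_points(mol, pts, clamp=1e6)
        assert ele[0] == pytest.approx(COULOMB_CONSTANT, rel=1e-12)
        _, ele_clamped, _ = comfa_values_at_points(mol, pts)
        assert ele_clamped[0] == 30.0

    def test_steric_zero_crossing(self):
        eps_c, rh_c = LJ_PARAMS["C"]
        rmin = 1.70 + rh_c
        r0 = rmin / 2 ** (1 / 6)
        s, _, _ = comfa_values_at_points(_atom(), np.array([[r0, 0, 0]]))
        assert s[0] == pytest.approx(0.0, abs=1e-9)

    def test_distant_point_decay(self):
        mol = _atom(charge=1.0)
        s, e, _ = comfa_values_at_points(mol, np.array([[12.0, 0, 0]]))
        assert abs(s[0]) < 1e-3
        assert abs(e[0]) < 3.0

    def test_probe_charge_scales_electrostatics_only(self, small_library):
        from fieldqsar.field_engine import ProbeParams
        mol = small_library.molecules[0]
        pts = np.array([[8.0, 1.0, 0.5], [0.0, 6.0, 1.0]])
        s1, e1, _ = comfa_values_at_points(mol, pts, ProbeParams(charge=1.0), clamp=1e9)
        s2, e2, _ = comfa_values_at_points(mol, pts, ProbeParams(charge=2.0), clamp=1e9)
        np.testing.assert_allclose(e2, 2 * e1, rtol=1e-12)
        np.testing.assert_allclose(s2, s1, rtol=1e-12)

    def test_brute_force_oracle(self, small_library):
        """Naive per-atom/per-point triple loop agrees with the production
        (vectorized) evaluation to 1e-10."""
        mols = small_library.molecules[:3]
        grid = fq.build_grid(mols, spacing=3.0, margin=1.0)
        block = fq.comfa_fields(mols, grid, clamp=30.0)
        pts = grid.points()
        for mi, mol in enumerate(mols):
            for pi in range(0, len(pts), 7):   # subsample points for speed
                steric = 0.0
                ele = 0.0
                for ai in range(mol.n_atoms):
                    r = max(np.linalg.norm(pts[pi] - mol.coords[ai]), 1e-6)
                    eps_a, rh_a = LJ_PARAMS.get(mol.elements[ai], (0.107, 1.70))
                    eps = math.sqrt(0.107 * eps_a)
                    rmin = 1.70 + rh_a
                    steric += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
                    ele += COULOMB_CONSTANT * mol.charges[ai] / r**2
                steric = min(max(steric, -30.0), 30.0)
                ele = min(max(ele, -30.0), 30.0)
                assert block.matrix[mi, pi] == pytest.approx(steric, abs=1e-10)
                assert block.matrix[mi, grid.n_points + pi] == pytest.approx(ele, abs=1e-10)

    def test_missing_frame_rejected(self, small_library):
        grid = fq.GridSpec(origin=(0, 0, 0), spacing=1.0, dimensions=(2, 2, 2))
        with pytest.raises(ValidationError, match="outside"):
            fq.comfa_fields(small_library.molecules[:1], grid)


class TestComsia:
    def test_no_donor_channel_zero(self):
        mol = _atom(charge=0.1, acceptor=True)
        vals = comsia_values_at_points(mol, np.array([[1.0, 0, 0]]))
        assert vals["D"][0] == 0.0
        assert vals["A"][0] != 0.0

    def test_gaussian_at_zero_distance(self):
        mol = _atom(charge=-0.3, hydrophobe=True)
        vals = comsia_values_at_points(mol, np.array([[0.0, 0.0, 0.0]]))
        assert vals["E"][0] == pytest.approx(0.3, rel=1e-12)     # -w, w = charge
        assert vals["H"][0] == pytest.approx(-1.0, rel=1e-12)
        assert vals["S"][0] == pytest.approx(-1.70**3, rel=1e-12)

    def test_identical_molecules_identical_rows(self, small_library):
        m = small_library.molecules[0]
        grid = fq.build_grid([m], 2.5, 3.0)
        block = fq.comsia_fields([m, m.copy()], grid)
        np.testing.assert_array_equal(block.matrix[0], block.matrix[1])

    def test_brute_force_oracle(self, small_library):
        mols = small_library.molecules[:2]
        grid = fq.build_grid(mols, spacing=3.0, margin=1.0)
        block = fq.comsia_fields(mols, grid, channels=("E", "H"), alpha=0.3)
        pts = grid.points()
        for mi, mol in enumerate(mols):
            for pi in range(0, len(pts), 5):
                e = sum(-q * math.exp(-0.3 * np.sum((pts[pi] - c) ** 2))
                        for q, c in zip(mol.charges, mol.coords))
                h = sum(-float(f) * math.exp(-0.3 * np.sum((pts[pi] - c) ** 2))
                        for f, c in zip(mol.flags["hydrophobe"], mol.coords))
                assert block.matrix[mi, pi] == pytest.approx(e, abs=1e-10)
                assert block.matrix[mi, grid.n_points + pi] == pytest.approx(h, abs=1e-10)

    def test_rigid_covariance(self, small_library, rng):
        """Moving molecules and evaluation points together changes nothing."""
        from scipy.spatial.transform import Rotation
        mol = small_library.molecules[0]
        pts = rng.normal(0, 4, (20, 3))
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        t = np.array([3.0, -1.0, 2.0])
        moved = mol.transformed(rot, t)
        base = comsia_values_at_points(mol, pts)
        shifted = comsia_values_at_points(moved, pts @ rot.T + t)
        for c in base:
            np.testing.assert_allclose(shifted[c], base[c], atol=1e-9)
        s0, e0, _ = comfa_values_at_points(mol, pts, clamp=1e9)
        s1, e1, _ = comfa_values_at_points(moved, pts @ rot.T + t, clamp=1e9)
        np.testing.assert_allclose(s1, s0, atol=1e-9)
        np.testing.assert_allclose(e1, e0, atol=1e-9)

    def test_bad_alpha(self):
        with pytest.raises(DomainError):
            comsia_values_at_points(_atom(), np.zeros((1, 3)), alpha=0.0)


class TestFilterAndScale:
    def test_constant_column_masked(self, small_library):
        grid = fq.build_grid(small_library.molecules, 2.0, 4.0)
        block = fq.comsia_fields(small_library.molecules, grid)
        out = fq.filter_and_scale(block, min_sd=0.05)
        sd = block.matrix.std(axis=0)
        assert not out.column_mask[sd < 0.05].any()
        assert out.column_mask[sd >= 0.05].all()

    def test_equal_variance_scaling(self, small_library):
        grid = fq.build_grid(small_library.molecules, 2.0, 4.0)
        block = fq.comsia_fields(small_library.molecules, grid, channels=("S", "E"))
        out = fq.filter_and_scale(block, min_sd=1e-4)
        labels = out.column_channels()
        total = {}
        design_scale = out.col_scale()
        for c in ("S", "E"):
            cols = (labels == c) & out.column_mask
            total[c] = np.sum((block.matrix[:, cols].std(axis=0) * design_scale[cols]) ** 2)
        assert total["S"] == pytest.approx(total["E"], rel=1e-9)

    def test_scale_factor_ratio(self):
        """Channels with raw variances v and 4v get factors in ratio 2:1."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, (20, 4))
        mat = np.hstack([base, 2 * rng.normal(0, 1, (20, 4))])
        grid = fq.GridSpec(origin=(0, 0, 0), spacing=1.0, dimensions=(4, 1, 1))
        block = fq.FieldBlock(matrix=mat, channels=["S", "E"], grid=grid,
                              ids=[str(i) for i in range(20)], unit="x")
        out = fq.filter_and_scale(block, min_sd=0.0)
        v_s = np.sum(mat[:, :4].std(axis=0) ** 2)
        v_e = np.sum(mat[:, 4:].std(axis=0) ** 2)
        assert out.block_scale["S"] / out.block_scale["E"] == \
            pytest.approx(np.sqrt(v_e / v_s), rel=1e-9)

    def test_all_masked_rejected(self):
        grid = fq.GridSpec(origin=(0, 0, 0), spacing=1.0, dimensions=(2, 1, 1))
        block = fq.FieldBlock(matrix=np.ones((5, 2)), channels=["S"], grid=grid,
                              ids=list("abcde"), unit="x")
        with pytest.raises(DegenerateInputError):
            fq.filter_and_scale(block, min_sd=0.05)
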