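"""Dihedrals, plane angles, virtual cystine modelling, superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ssforge import constants as K
from ssforge import fixtures as fx
from ssforge import geometry as g
from ssforge import structure_io as sio
from ssforge.errors import ContractError, DegenerateGeometryError, MissingAtomError

from oracles import grid_search_rmsd


def random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.uniform(-20, 20, size=3)
    return lambda x: rot.apply(x) + shift


class TestDihedral:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),      # cis
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),    # trans
            ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),     # hand-derived
        ],
    )
    def test_reference_angles(self, points, expected):
        assert g.dihedral(*map(np.array, points)) == pytest.approx(expected, abs=1e-9)

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            g.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_rigid_invariance_and_mirror_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        try:
            ang = g.dihedral(*pts)
        except DegenerateGeometryError:
            return
        moved = random_rigid(rng)(pts)
        assert g.dihedral(*moved) == pytest.approx(ang, abs=1e-7)
        mirrored = pts * np.array([1, 1, -1])
        assert g.dihedral(*mirrored) == pytest.approx(-ang, abs=1e-7) or (
            abs(ang) == pytest.approx(180.0, abs=1e-7)
        )


class TestPlaneDihedral:
    def test_identical_planes_are_zero(self):
        t = [np.array(p, float) for p in [(0, 0, 0), (1, 0, 0), (0, 1, 0)]]
        assert g.plane_dihedral(*t, *t) == pytest.approx(0.0, abs=1e-9)

    def test_reversed_winding_is_180(self):
        a = [np.array(p, float) for p in [(0, 0, 0), (1, 0, 0), (0, 1, 0)]]
        b = [a[0], a[2], a[1]]
        assert g.plane_dihedral(*a, *b) == pytest.approx(180.0, abs=1e-9)

    def test_orthogonal_planes_are_90(self):
        a = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]   # z = 0
        b = [(0, 0, 0), (0, 1, 0), (0, 0, 1)]   # x = 0
        assert g.plane_dihedral(*a, *b) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_triple_raises(self):
        with pytest.raises(DegenerateGeometryError):
            g.plane_dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (0, 0, 0), (1, 0, 0), (0, 1, 0))


class TestSuperpose:
    def test_identical_sets(self, rng):
        pts = rng.normal(size=(6, 3)) * 5
        res = g.superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_rigid_copy(self, rng):
        pts = rng.normal(size=(5, 3)) * 5
        rot = Rotation.from_euler("z", 37, degrees=True)
        moved = rot.apply(pts) + np.array([1.0, 2.0, 3.0])
        res = g.superpose(moved, pts)
        assert res.rmsd <= 1e-8
        np.testing.assert_allclose(res.apply(moved), pts, atol=1e-8)

    def test_square_with_displaced_corner_matches_grid_oracle(self):
        fixed = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        moving = fixed.copy()
        moving[2, 2] = 1.0
        got = g.superpose(moving, fixed).rmsd
        assert got == pytest.approx(grid_search_rmsd(moving, fixed), abs=1e-3)

    def test_rmsd_is_symmetric(self, rng):
        a = rng.normal(size=(7, 3)) * 4
        b = a + rng.normal(size=(7, 3)) * 0.5
        assert g.superpose(a, b).rmsd == pytest.approx(g.superpose(b, a).rmsd, abs=1e-9)

    def test_rotation_is_proper_even_for_mirrored_input(self, rng):
        pts = rng.normal(size=(6, 3)) * 3
        mirrored = pts * np.array([1, 1, -1])
        res = g.superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [np.zeros((2, 3)), np.zeros((4, 2))])
    def test_contract_errors(self, bad):
        with pytest.raises(ContractError):
            g.superpose(bad, np.zeros((4, 3)))


class TestModelCystine:
    def test_self_consistency_on_ideal_cysteine(self, bundle):
        st, key_a, key_b = bundle
        pair = sio.make_pair(st, key_a, key_b)
        res_a = st.get_residue(key_a)
        chi1 = g.dihedral(res_a.atoms["N"], res_a.atoms["CA"],
                          res_a.atoms["CB"], res_a.atoms["SG"])
        models = g.model_cystine(st, pair, rotamer_set=[chi1])
        best = min(models, key=lambda m: np.linalg.norm(m.sg_a - res_a.atoms["SG"]))
        assert np.linalg.norm(best.sg_a - res_a.atoms["SG"]) < 0.1

    def test_glycine_gets_virtual_cbeta(self):
        st = fx.make_helix(12)
        for res in st.chains[0].residues:
            res.res_name = "GLY"
            res.atoms.pop("CB", None)
        pair = sio.make_pair(st, ("A", 3, ""), ("A", 9, ""))
        models = g.model_cystine(st, pair)
        assert len(models) == 9
        assert all(np.isfinite(m.sg_a).all() and np.isfinite(m.sg_b).all() for m in models)

    def test_rotamer_cartesian_product(self):
        st = fx.make_helix(12)
        pair = sio.make_pair(st, ("A", 3, ""), ("A", 9, ""))
        assert len(g.model_cystine(st, pair, rotamer_set=(-60, 60, 180))) == 9

    def test_missing_backbone_atom_reports_residue_and_atom(self):
        st = fx.make_helix(12)
        del st.chains[0].residues[2].atoms["N"]
        pair = sio.make_pair(st, ("A", 3, ""), ("A", 9, ""))
        with pytest.raises(MissingAtomError, match="N"):
            g.model_cystine(st, pair)


class TestExtractGeometry:
    def test_native_fixture_reads_back_generator_parameters(self, bundle):
        st, key_a, key_b = bundle
        geom = g.extract_geometry(st, sio.make_pair(st, key_a, key_b))
        assert geom.sg_sg == pytest.approx(2.05, abs=0.01)
        assert geom.chi.chi3 == pytest.approx(97.0, abs=0.5)

    def test_duplicate_distance_consistency(self, bundle):
        st, key_a, key_b = bundle
        geom = g.extract_geometry(st, sio.make_pair(st, key_a, key_b))
        assert geom.ca_ca == geom.cross_distances["d_CA_CA"]
        assert geom.cb_cb == geom.cross_distances["d_CB_CB"]
        assert geom.sg_sg == geom.cross_distances["d_SG_SG"]
        assert len(geom.features()) == 44
        assert all(v > 0 for k, v in geom.cross_distances.items())

    def test_rigid_invariance(self, bundle, rng):
        import copy

        st, key_a, key_b = bundle
        st = copy.deepcopy(st)
        pair = sio.make_pair(st, key_a, key_b)
        before = g.extract_geometry(st, pair, use_modeled=True)
        move = random_rigid(rng)
        for res in st.residues():
            for name in res.atoms:
                res.atoms[name] = move(res.atoms[name][None, :])[0]
        after = g.extract_geometry(st, pair, use_modeled=True)
        for name, value in before.features().items():
            assert after.features()[name] == pytest.approx(value, abs=1e-6), name

    def test_far_pair_cannot_close_bond(self):
        # Cα-Cα = 12 Å leaves every rotamer with Sγ-Sγ over 5 Å
        st = fx.make_helix(30)
        residues = st.chains[0].residues
        pair = None
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                d = np.linalg.norm(residues[i].atoms["CA"] - residues[j].atoms["CA"])
                if 11.5 <= d <= 13.0:
                    pair = sio.make_pair(st, residues[i].key, residues[j].key)
                    break
            if pair:
                break
        assert pair is not None
        models = g.model_cystine(st, pair)
        assert min(m.sg_sg for m in models) > 5.0

    def test_triangle_inequality_bound_over_rotamers(self, bundle):
        st, _, _ = bundle
        keys = [r.key for r in st.residues()]
        for ka, kb in [(keys[0], keys[10]), (keys[2], keys[20]), (keys[5], keys[25])]:
            pair = sio.make_pair(st, ka, kb)
            geom = g.extract_geometry(st, pair, use_modeled=True)
            models = g.model_cystine(st, pair)
            assert min(m.sg_sg for m in models) >= geom.cb_cb - 2 * K.BOND_CB_SG - 1e-9

    def test_chi_swap_symmetry(self, bundle):
        st, key_a, key_b = bundle
        geom = g.extract_geometry(st, sio.make_pair(st, key_a, key_b))
        res_a = st.get_residue(key_a)
        res_b = st.get_residue(key_b)
        atoms = lambda r: {n: r.atoms[n] for n in ("N", "CA", "CB", "SG")}
        swapped = g._geometry_from_atoms(
            {**atoms(res_b), "C": res_b.atoms["C"], "O": res_b.atoms["O"]},
            {**atoms(res_a), "C": res_a.atoms["C"], "O": res_a.atoms["O"]},
        )
        assert swapped.chi.chi1 == pytest.approx(geom.chi.chi1_prime, abs=1e-9)
        assert swapped.chi.chi2 == pytest.approx(geom.chi.chi2_prime, abs=1e-9)
        assert swapped.chi.chi3 == pytest.approx(geom.chi.chi3, abs=1e-9)
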