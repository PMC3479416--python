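"""Shrake-Rupley SASA, relative SASA and interface classification."""

import numpy as np
import pytest

from chidist.sasa import SurfaceClass, atom_radius, classify_surface, \
    delta_sasa, relative_sasa, residue_sasa, shrake_rupley, sphere_points
from chidist.structure_io import Atom, Residue, Structure, extract_monomer


def single_atom_structure(name="CA", element="C", coords=(0, 0, 0),
                          res_type="GLY"):
    s = Structure("single")
    res = Residue("A", 1, "", res_type)
    res.atoms.append(Atom(name, element, np.asarray(coords, dtype=float)))
    s.chains["A"] = [res]
    return s


class TestAtomRadius:
    def test_backbone_nitrogen(self):
        assert atom_radius("N", "N", "SER") == 1.65

    def test_alpha_carbon_is_tetrahedral(self):
        assert atom_radius("CA", "C", "SER") == 1.87

    def test_aromatic_carbon_is_trigonal(self):
        assert atom_radius("CZ", "C", "PHE") == 1.76
        assert atom_radius("CZ", "C", "LYS") == 1.87  # aliphatic context

    def test_unknown_element_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            r = atom_radius("XX", "Q", "SER")
        assert r == 1.80


class TestShrakeRupley:
    def test_isolated_atom_matches_closed_form(self):
        s = single_atom_structure()
        area = shrake_rupley(s)[0]
        expected = 4 * np.pi * (1.87 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=1e-12)  # no occlusion

    def test_distant_atoms_sum_like_isolated_spheres(self):
        s2 = Structure("pair")
        for i, x in enumerate([0.0, 100.0]):
            r = Residue("A", i + 1, "", "GLY")
            r.atoms.append(Atom("CA", "C", np.array([x, 0.0, 0.0])))
            s2.chains.setdefault("A", []).append(r)
        areas = shrake_rupley(s2)
        expected = 4 * np.pi * (1.87 + 1.4) ** 2
        np.testing.assert_allclose(areas, expected, rtol=1e-12)

    def test_close_packed_neighbors_bury_central_atom(self):
        """Central atom in a 12-neighbor cuboctahedral (fcc) shell: both the
        production code and a brute-force random-point oracle agree it is
        nearly fully buried."""
        r_atom, probe = 1.87, 1.4
        d = 2 * r_atom  # touching van der Waals spheres
        dirs = []
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            for si in (1, -1):
                for sj in (1, -1):
                    v = np.zeros(3)
                    v[i], v[j] = si, sj
                    dirs.append(v / np.sqrt(2))
        s = Structure("fcc")
        center = Residue("A", 1, "", "GLY")
        center.atoms.append(Atom("CA", "C", np.zeros(3)))
        s.chains["A"] = [center]
        for k, v in enumerate(dirs):
            res = Residue("A", k + 2, "", "GLY")
            res.atoms.append(Atom("CA", "C", d * v))
            s.chains["A"].append(res)
        isolated = 4 * np.pi * (r_atom + probe) ** 2
        area = shrake_rupley(s)[0]
        assert area < 0.05 * isolated

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= r_atom + probe
        buried = np.zeros(len(pts), dtype=bool)
        for v in dirs:
            buried |= np.linalg.norm(pts - d * v, axis=1) < r_atom + probe
        oracle_frac = 1.0 - buried.mean()
        assert oracle_frac < 0.05
        assert area / isolated == pytest.approx(oracle_frac, abs=0.01)

    def test_total_sasa_rotation_invariant(self, toy_complex):
        from scipy.spatial.transform import Rotation
        total = shrake_rupley(toy_complex).sum()
        rot = Rotation.from_euler("zyx", [31.0, -47.0, 113.0],
                                  degrees=True).as_matrix()
        rotated = Structure("rot")
        for cid, chain in toy_complex.chains.items():
            out = []
            for res in chain:
                r2 = Residue(res.chain_id, res.seq_num, res.icode,
                             res.res_type)
                for a in res.atoms:
                    r2.atoms.append(Atom(a.name, a.element,
                                         rot @ a.coords + 5.0))
                out.append(r2)
            rotated.chains[cid] = out
        assert shrake_rupley(rotated).sum() == pytest.approx(total, rel=0.005)

    def test_invalid_point_count(self):
        with pytest.raises(ValueError):
            shrake_rupley(single_atom_structure(), n_points=0)

    def test_sphere_points_lie_on_unit_sphere(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)

    def test_agrees_with_biotite_on_toy_structure(self, toy_complex):
        """Independent oracle: biotite's Shrake-Rupley with identical radii."""
        import biotite.structure as bst
        from chidist.sasa import _structure_arrays
        coords, radii, _ = _structure_arrays(toy_complex)
        arr = bst.AtomArray(len(coords))
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(
            [a.element for a in toy_complex.atoms], dtype="U2")
        arr.res_id = np.arange(len(coords))
        arr.atom_name = np.array(
            [a.name for a in toy_complex.atoms], dtype="U6")
        ours = shrake_rupley(toy_complex)
        ref = bst.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                       point_number=960)
        np.testing.assert_allclose(ours.sum(), ref.sum(), rtol=0.01)


class TestResidueAggregation:
    def test_residue_sum_and_conservation(self, toy_complex):
        per_atom = shrake_rupley(toy_complex)
        records = residue_sasa(per_atom, toy_complex)
        assert sum(r.abs_sasa for r in records) == pytest.approx(
            per_atom.sum())
        assert len(records) == len(toy_complex.residues)


class TestRelativeAndDelta:
    @pytest.mark.parametrize("abs_sasa,expected",
                             [(155.0, 1.0), (0.0, 0.0), (77.5, 0.5)])
    def test_relative_sasa_fractions(self, abs_sasa, expected):
        assert relative_sasa(abs_sasa, "SER") == pytest.approx(expected)

    def test_missing_reference_errors(self):
        with pytest.raises(KeyError):
            relative_sasa(10.0, "MSE")

    @pytest.mark.parametrize("mono,cplx,expected",
                             [(50.0, 30.0, 20.0), (50.0, 50.0, 0.0),
                              (50.0, 50.0000001, 0.0)])
    def test_delta_sasa(self, mono, cplx, expected):
        assert delta_sasa(mono, cplx) == pytest.approx(expected)

    def test_delta_nonnegative_for_extracted_monomers(self, toy_complex):
        cplx = {r.residue_key: r.abs_sasa for r in residue_sasa(
            shrake_rupley(toy_complex), toy_complex)}
        for chains in ({"A"}, {"B"}):
            mono = extract_monomer(toy_complex, chains)
            for rec in residue_sasa(shrake_rupley(mono), mono):
                assert delta_sasa(rec.abs_sasa,
                                  cplx[rec.residue_key]) >= 0.0


class TestClassifySurface:
    @pytest.mark.parametrize("rel_b,rel_u,ds,expected", [
        (0.30, 0.30, 5.0, SurfaceClass.INTERFACE),
        (0.30, 0.30, 0.5, SurfaceClass.NON_INTERFACE),
        (0.20, 0.30, 5.0, SurfaceClass.EXCLUDED),
        (0.30, 0.20, 5.0, SurfaceClass.EXCLUDED),
        (0.30, None, 5.0, SurfaceClass.INTERFACE),   # bound-only case
        (0.30, None, 0.5, SurfaceClass.NON_INTERFACE),
    ])
    def test_classification_rules(self, rel_b, rel_u, ds, expected):
        assert classify_surface(rel_b, rel_u, ds) is expected

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        for _ in range(200):
            rel_b, rel_u = rng.uniform(0, 1.2, size=2)
            ds = rng.uniform(0, 10)
            cls = classify_surface(rel_b, rel_u, ds)
            assert cls in (SurfaceClass.INTERFACE, SurfaceClass.NON_INTERFACE,
                           SurfaceClass.EXCLUDED)
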