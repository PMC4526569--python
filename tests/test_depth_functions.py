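"""Chakravarty-style depth, DPX and half-sphere exposure semantics."""

import numpy as np
import pytest

from hullprot.depth_functions import (
    chakravarty_depth,
    dpx,
    half_sphere_exposure,
    read_depth_output,
    read_dpx_output,
)
from hullprot.fixtures import make_globule, make_mini_pdb, structure_from_points
from hullprot.sasa_rsa import atom_sasa, residue_rsa
from hullprot.structure_model import read_pdb

from .oracles import brute_force_hse

PROBE = 1.4


class TestChakravartyDepth:
    def test_isolated_atom_depth_is_expanded_radius(self):
        st = structure_from_points(np.zeros((1, 3)))
        sasa = atom_sasa(st, probe=PROBE, keep_samples=True)
        depth = chakravarty_depth(st, sasa)
        # every surface sample sits at r_vdw + probe from the centre
        assert depth[("A", 1, "")] == pytest.approx(1.70 + PROBE, abs=1e-6)

    def test_requires_samples(self, tripeptide):
        sasa = atom_sasa(tripeptide, probe=PROBE, keep_samples=False)
        with pytest.raises(ValueError, match="keep_samples"):
            chakravarty_depth(tripeptide, sasa)

    def test_matches_bruteforce_nearest_sample(self):
        st, _ = make_globule(n_residues=40, seed=21)
        sasa = atom_sasa(st, probe=PROBE, keep_samples=True)
        depth = chakravarty_depth(st, sasa)
        coords = st.atom_coords()
        samples = sasa.surface_samples
        for i, res in enumerate(st):
            direct = np.sqrt(((samples - coords[i]) ** 2).sum(axis=1)).min()
            assert depth[res.key] == pytest.approx(direct)

    def test_surface_atoms_are_shallow(self):
        st, _ = make_globule(n_residues=60, seed=22)
        sasa = atom_sasa(st, probe=PROBE, n_points=960, keep_samples=True)
        depth = chakravarty_depth(st, sasa)
        # atoms with ASA > 0 carry their own surface samples
        spacing = np.sqrt(4 * np.pi * (3.0 + PROBE) ** 2 / 960)
        for i, res in enumerate(st):
            if sasa.asa[i] > 0:
                assert depth[res.key] <= 3.0 + PROBE + spacing


class TestDpx:
    def test_zero_when_everything_accessible(self, tripeptide):
        sasa = atom_sasa(tripeptide, probe=PROBE)
        vals = dpx(tripeptide, sasa)
        assert all(v == 0.0 for v in vals.values())

    def test_buried_atom_distance_to_nearest_exposed(self, tmp_path):
        # a line of touching residue-sized spheres: the middle one is fully
        # occluded laterally only in a crowd; instead bury it inside a cage
        centre = np.zeros((1, 3))
        cage = 3.5 * np.array(
            [[x, y, z] for x in (-1, 0, 1) for y in (-1, 0, 1) for z in (-1, 0, 1)
             if (x, y, z) != (0, 0, 0)]
        )
        st = structure_from_points(np.vstack([centre, cage]), sphere_radius=3.0)
        sasa = atom_sasa(st, probe=PROBE)
        assert sasa.asa[0] == 0.0  # centre is buried
        vals = dpx(st, sasa)
        coords = st.atom_coords()
        accessible = np.flatnonzero(sasa.asa > 0)
        direct = min(np.linalg.norm(coords[0] - coords[j]) for j in accessible)
        assert vals[("A", 1, "")] == pytest.approx(direct)
        assert direct == pytest.approx(3.5)

    def test_no_accessible_atoms_raises(self, tripeptide):
        sasa = atom_sasa(tripeptide, probe=PROBE)
        sasa.asa[:] = 0.0
        with pytest.raises(ValueError, match="accessible"):
            dpx(tripeptide, sasa)


class TestHalfSphereExposure:
    def test_no_neighbours_gives_zero_zero(self):
        st = structure_from_points(np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]))
        hse = half_sphere_exposure(st, radius=13.0, mode="A")
        assert hse[("A", 1, "")] == (0, 0)  # chain partner is outside the sphere

    def test_partition_invariant(self, globule):
        st, _ = globule
        from scipy.spatial import cKDTree

        ca = st.atom_coords()
        tree = cKDTree(ca)
        for mode in ("A", "B"):
            hse = half_sphere_exposure(st, radius=13.0, mode=mode)
            for i, res in enumerate(st):
                total = len(tree.query_ball_point(ca[i], 13.0)) - 1
                assert sum(hse[res.key]) == total

    @pytest.mark.parametrize("mode", ["A", "B"])
    def test_matches_bruteforce_on_helix(self, mode, tmp_path):
        # 30-residue ideal-ish helix with Cβ branches
        n = 30
        spec = []
        for i in range(n):
            theta = 100.0 * np.pi / 180.0 * i
            x, y, z = 2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i
            atoms = [("CA", "C", x, y, z)]
            if i % 3:  # leave some residues Cβ-less to exercise the fallback
                atoms.append(("CB", "C", 1.5 * x, 1.5 * y, z))
            spec.append({"chain": "A", "seq_num": i + 1, "aa3": "ALA", "atoms": atoms})
        pdb = tmp_path / "helix.pdb"
        pdb.write_text(make_mini_pdb(spec))
        st = read_pdb(pdb)
        ours = half_sphere_exposure(st, radius=13.0, mode=mode)
        theirs = brute_force_hse(st, 13.0, mode)
        assert ours == theirs

    def test_single_residue_chain_counts_all_down(self):
        st = structure_from_points(np.array([[0.0, 0.0, 0.0]]))
        with pytest.warns(UserWarning, match="single"):
            hse = half_sphere_exposure(st, mode="A")
        assert hse[("A", 1, "")] == (0, 0)

    def test_depths_anticorrelate_with_rsa(self):
        # layered structure with a solvent-excluded core: depth grows inward
        # while RSA falls, mirroring the anticorrelation seen on real antigens
        from hullprot.fixtures import make_shell_cloud

        cloud = make_shell_cloud(4, 300, (24.0, 18.0, 12.0, 6.0), (0.0,) * 4,
                                 seed=1)
        st = structure_from_points(cloud.points, sphere_radius=3.0)
        sasa = atom_sasa(st, probe=PROBE, keep_samples=True)
        rsa = residue_rsa(sasa, st)
        chak = chakravarty_depth(st, sasa)
        dpx_vals = dpx(st, sasa)
        keys = list(rsa.rsa)
        r = np.array([rsa.rsa[k] for k in keys])
        c = np.array([chak[k] for k in keys])
        d = np.array([dpx_vals[k] for k in keys])
        assert np.corrcoef(c, r)[0, 1] < -0.5
        assert np.corrcoef(d, r)[0, 1] < -0.5
        assert np.all(c >= 0) and np.all(d >= 0)


class TestExternalReaders:
    def test_depth_output_reader(self, tmp_path):
        f = tmp_path / "x.depth"
        f.write_text(
            "# chain:res restype depth\nA:1 ALA 4.25 3.1\nA:2 GLY 5.50 4.2\n"
        )
        vals = read_depth_output(f)
        assert vals[("A", 1, "")] == pytest.approx(4.25)

    def test_dpx_output_reader(self, tmp_path):
        f = tmp_path / "x.dpx"
        f.write_text("A 1 ALA 0.00\nA 2 GLY 1.75\n")
        vals = read_dpx_output(f)
        assert vals[("A", 2, "")] == pytest.approx(1.75)
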