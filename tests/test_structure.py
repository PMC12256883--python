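"""PDB IO, Gaussian network model, hinge calling, SASA and interface search."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from structmut import simulate
from structmut import structure as st

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.000   2.000   0.500  1.00  0.00           C
ATOM      5  CA  SER A   3       7.500   2.500   1.000  1.00  0.00           C
END
"""


def _chain_structure(n=50, spacing=3.8):
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return st.ProteinStructure.from_calpha(coords)


class TestPdbIO:
    def test_three_residue_fixture(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_3RES)
        s = st.read_pdb(path)
        assert s.n_residues == 3
        assert (s.calpha_index >= 0).all()
        assert s.calpha_coords().shape == (3, 3)

    def test_multi_model_returns_equal_residue_counts(self, tmp_path):
        s, _ = simulate.make_two_domain_structure(seed=1)
        ens_coords = [s.coords, s.coords + 1.0]
        frames = [
            st.ProteinStructure.from_calpha(c) for c in ens_coords
        ]
        path = tmp_path / "two.pdb"
        st.write_pdb(frames, path)
        models = st.read_pdb(path, model="all")
        assert len(models) == 2
        assert models[0].n_residues == models[1].n_residues == s.n_residues

    def test_generator_round_trip_within_format_precision(self, tmp_path):
        s, _ = simulate.make_two_domain_structure(seed=2)
        path = tmp_path / "gen.pdb"
        st.write_pdb(s, path)
        back = st.read_pdb(path)
        assert np.abs(back.coords - s.coords).max() < 5e-3

    def test_unreadable_file_raises(self, tmp_path):
        path = tmp_path / "junk.pdb"
        path.write_bytes(b"\x00\x01\x02 not a pdb")
        with pytest.raises(ValueError):
            st.read_pdb(path)


class TestGnm:
    def test_two_node_closed_form(self):
        s = st.ProteinStructure.from_calpha(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        enm = st.build_gnm(s, cutoff=10.0)
        assert np.allclose(enm.kirchhoff, [[1, -1], [-1, 1]])
        assert np.allclose(enm.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_row_sums_zero_and_spectrum_nonnegative(self, two_domain):
        s, _ = two_domain
        enm = st.build_gnm(s)
        assert np.abs(enm.kirchhoff.sum(axis=1)).max() < 1e-9
        assert enm.eigenvalues.min() > -1e-9
        assert enm.n_zero_modes == 1

    def test_matches_independent_dense_solver(self):
        """Chain and random structures vs an independently built Kirchhoff."""
        rng = np.random.default_rng(8)
        for coords in (
            _chain_structure(50).coords,
            rng.uniform(0, 30, size=(80, 3)),
        ):
            s = st.ProteinStructure.from_calpha(coords)
            enm = st.build_gnm(s, cutoff=10.0)
            n = len(coords)
            k = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    if i != j and np.linalg.norm(coords[i] - coords[j]) <= 10.0:
                        k[i, j] = -1.0
            np.fill_diagonal(k, -k.sum(axis=1))
            assert np.abs(enm.kirchhoff - k).max() == 0.0
            oracle = np.linalg.eigvalsh(k)
            assert np.abs(enm.eigenvalues - oracle).max() < 1e-8

    def test_zero_modes_count_connected_components(self):
        rng = np.random.default_rng(3)
        blobs = [rng.normal(scale=3, size=(12, 3)) + off for off in
                 (np.zeros(3), np.array([50.0, 0, 0]), np.array([0, 80.0, 0]))]
        coords = np.vstack(blobs)
        s = st.ProteinStructure.from_calpha(coords)
        enm = st.build_gnm(s, cutoff=10.0)
        # graph-traversal oracle
        n = len(coords)
        adj = [
            [j for j in range(n)
             if j != i and np.linalg.norm(coords[i] - coords[j]) <= 10.0]
            for i in range(n)
        ]
        seen, comps = set(), 0
        for start in range(n):
            if start in seen:
                continue
            comps += 1
            stack = [start]
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                stack.extend(adj[v])
        assert enm.n_zero_modes == comps


class TestModes:
    def test_two_node_mode_closed_form(self):
        s = st.ProteinStructure.from_calpha(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        enm = st.build_gnm(s)
        v = st.mode(enm, 1)
        assert np.allclose(v, [1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_modes_orthogonal(self, two_domain):
        s, _ = two_domain
        enm = st.build_gnm(s)
        assert abs(np.dot(st.mode(enm, 1), st.mode(enm, 2))) < 1e-6

    def test_chain_slowest_mode_flips_once_near_midpoint(self):
        s = _chain_structure(51)
        enm = st.build_gnm(s)
        v = st.mode(enm, 1)
        signs = np.sign(v[np.abs(v) > 1e-10])
        flips = np.flatnonzero(np.diff(signs) != 0)
        assert len(flips) == 1
        assert abs(flips[0] - 25) <= 3

    def test_out_of_range_mode_raises(self):
        s = st.ProteinStructure.from_calpha(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        enm = st.build_gnm(s)
        with pytest.raises(IndexError):
            st.mode(enm, 2)


class TestHinges:
    def test_sign_flip_marks_hinge(self):
        s = st.ProteinStructure.from_calpha(np.zeros((4, 3)) + np.arange(4)[:, None])
        h = st.find_hinges(np.array([1.0, 1.0, -1.0, -1.0]), s, tolerance=0.0)
        assert [num for _, num in h.residues] == [3]

    def test_all_positive_mode_has_no_hinge(self):
        s = st.ProteinStructure.from_calpha(np.zeros((4, 3)) + np.arange(4)[:, None])
        h = st.find_hinges(np.array([1.0, 0.9, 0.8, 0.7]), s, tolerance=0.0)
        assert h.residues == []

    def test_near_zero_plateau_included(self):
        s = st.ProteinStructure.from_calpha(np.zeros((5, 3)) + np.arange(5)[:, None])
        v = np.array([1.0, 0.01, 0.0, -0.01, -1.0])
        h = st.find_hinges(v, s)  # default tolerance 0.05 * max
        nums = [num for _, num in h.residues]
        assert set(nums) >= {2, 3, 4}

    def test_linker_hinge_on_two_domain_structure(self, two_domain):
        s, truth = two_domain
        enm = st.build_gnm(s)
        h = st.find_hinges(st.mode(enm, 1), s, mode_index=1)
        lo = truth.params["linker_start"]
        hi = truth.params["linker_end"]
        assert any(lo <= num <= hi for _, num in h.residues)


class TestSasa:
    def test_isolated_carbon_analytic_area(self):
        s = st.ProteinStructure.from_calpha(np.array([[0.0, 0, 0]]))
        prof = st.sasa(s)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(prof.area[0] - exact) / exact < 0.02

    def test_coincident_atoms_count_once(self):
        s = st.ProteinStructure.from_calpha(np.zeros((2, 3)))
        prof = st.sasa(s)
        single = 4 * np.pi * 3.1**2
        assert abs(prof.area.sum() - single) / single < 0.02

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=8, size=(40, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        a = st.sasa(st.ProteinStructure.from_calpha(coords)).area
        b = st.sasa(
            st.ProteinStructure.from_calpha(coords @ rot.T + np.array([3.0, -7.0, 11.0]))
        ).area
        assert np.abs(a - b).max() / a.max() < 1e-6

    def test_unknown_element_raises_naming_atom(self):
        s = st.ProteinStructure.from_calpha(np.zeros((1, 3)))
        s.elements = np.array(["ZZ"])
        with pytest.raises(ValueError, match="ZZ"):
            st.sasa(s)

    def test_buried_rule_threshold(self):
        rng = np.random.default_rng(4)
        s = st.ProteinStructure.from_calpha(rng.normal(scale=6, size=(60, 3)))
        prof = st.sasa(s)
        assert (prof.buried(20.0) == (prof.area <= 20.0)).all()

    def test_agrees_with_mdtraj_oracle(self, two_domain):
        md = pytest.importorskip("mdtraj")
        s, _ = two_domain
        prof = st.sasa(s)
        top = md.Topology()
        chain = top.add_chain()
        for i in range(s.n_residues):
            res = top.add_residue("ALA", chain)
            top.add_atom("CA", md.element.carbon, res)
        traj = md.Trajectory(s.coords[None] / 10.0, top)
        oracle = (
            md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960, mode="residue")[0]
            * 100.0
        )
        rel = np.abs(prof.area - oracle) / np.maximum(oracle, 1.0)
        assert rel.max() < 0.05


class TestInterfaceAndDistance:
    def test_cutoff_boundary(self):
        a = st.ProteinStructure.from_calpha(np.array([[0.0, 0, 0]]))
        near = st.ProteinStructure.from_calpha(np.array([[9.9, 0, 0]]))
        far = st.ProteinStructure.from_calpha(np.array([[10.1, 0, 0]]))
        assert st.interface_residues(a, near) == [("A", 1)]
        assert st.interface_residues(a, far) == []

    def test_superposed_structures_fully_interfacial(self, two_domain):
        s, _ = two_domain
        assert len(st.interface_residues(s, s)) == s.n_residues

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(9)
        a = st.ProteinStructure.from_calpha(rng.uniform(0, 60, size=(200, 3)))
        b = st.ProteinStructure.from_calpha(rng.uniform(30, 90, size=(200, 3)))
        fast = set(st.interface_residues(a, b, cutoff=10.0))
        slow = set()
        ids = a.residue_ids()
        for i in range(a.n_atoms):
            for j in range(b.n_atoms):
                if np.linalg.norm(a.coords[i] - b.coords[j]) <= 10.0:
                    slow.add(ids[a.atom_res_index[i]])
        assert fast == slow

    def test_distance_zero_at_targets(self, two_domain):
        s, _ = two_domain
        d = st.distance_to_residue_set(s, [5, 40])
        assert d[4] == 0.0 and d[39] == 0.0

    def test_two_residue_distance(self):
        s = st.ProteinStructure.from_calpha(np.array([[0.0, 0, 0], [7.0, 0, 0]]))
        d = st.distance_to_residue_set(s, [1])
        assert d[1] == pytest.approx(7.0)

    def test_distance_matches_brute_force(self, two_domain):
        s, _ = two_domain
        targets = [3, 17, 50]
        d = st.distance_to_residue_set(s, targets)
        ca = s.calpha_coords()
        for i in range(s.n_residues):
            expected = min(np.linalg.norm(ca[i] - ca[t - 1]) for t in targets)
            assert d[i] == pytest.approx(expected)

    def test_missing_target_raises(self, two_domain):
        s, _ = two_domain
        with pytest.raises(KeyError):
            st.distance_to_residue_set(s, [9999])
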