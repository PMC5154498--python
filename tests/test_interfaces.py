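import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import protomem as pm
from protomem.interfaces import (ContactMap, canonicalize, cluster_interfaces,
                                 detect_oligomers, is_dimer, kabsch_rmsd,
                                 map_dissimilarity)
from protomem.topology import ProteinTopology, SystemTopology
from protomem.trajectory import Trajectory

from test_pair_profiles import two_protein_traj


def toy_pair_system(offsets, box=20.0):
    """Two 20-residue straight 'protomers' with prescribed bead offsets."""
    n_res = 20
    resnum = np.arange(65, 65 + n_res)
    hmap = {"TM1": (65, 74), "TM2": (75, 84)}
    pos1 = np.zeros((n_res, 3))
    pos1[:, 2] = np.linspace(-2, 2, n_res)
    pos1[:, 0] = 5.0
    pos1[:, 1] = 10.0
    pos2 = pos1.copy()
    pos2[:, 0] = 5.0 + offsets
    proteins = [
        ProteinTopology(0, "inactive", resnum, np.arange(n_res), helix_map=hmap),
        ProteinTopology(1, "inactive", resnum, n_res + np.arange(n_res),
                        helix_map=hmap),
    ]
    topo = SystemTopology(
        species=[], lipid_species_index=np.empty(0, int),
        lipid_leaflet=np.empty(0, int), lipid_first_bead=np.empty(0, int),
        proteins=proteins, box=np.array([box, box, 11.0]))
    return topo, np.concatenate([pos1, pos2])


class TestContactMap:
    def test_cutoff_is_0p8_inclusive(self):
        topo, pos = toy_pair_system(0.79)
        cm = pm.contact_map(pos, topo, 0, 1)
        assert cm.D.diagonal().all()
        topo, pos = toy_pair_system(0.81)
        cm = pm.contact_map(pos, topo, 0, 1)
        assert cm.D.sum() == 0

    def test_matches_brute_force_all_pairs(self, rng):
        topo, pos = toy_pair_system(0.5)
        pos = pos + rng.normal(0, 0.4, pos.shape)
        cm = pm.contact_map(pos, topo, 0, 1)
        for i in range(20):
            for j in range(20):
                d = np.linalg.norm(pm.min_image_displacement(
                    pos[i], pos[20 + j], topo.box))
                assert cm.D[i, j] == (d <= 0.8)

    def test_transposing_protomer_order_transposes_map(self):
        topo, pos = toy_pair_system(0.5)
        a = pm.contact_map(pos, topo, 0, 1)
        b = pm.contact_map(pos, topo, 1, 0)
        assert np.array_equal(a.D, b.D.T)

    def test_invariant_under_global_translation(self):
        topo, pos = toy_pair_system(0.5)
        a = pm.contact_map(pos, topo, 0, 1)
        shifted = pos + np.array([13.0, 7.0, 0.0])
        shifted[:, :2] %= 20.0
        b = pm.contact_map(shifted, topo, 0, 1)
        assert np.array_equal(a.D, b.D)


class TestDimerRule:
    def _map_with_contacts(self, n1, n2):
        D = np.zeros((40, 40), dtype=np.uint8)
        for k in range(max(n1, n2)):
            D[min(k, n1 - 1), min(k, n2 - 1)] = 1
        return ContactMap((0, 1), ("inactive", "inactive"), 0, D)

    def test_ten_residues_each_side_is_a_dimer(self):
        assert is_dimer(self._map_with_contacts(10, 10))

    def test_nine_on_one_side_is_not(self):
        assert not is_dimer(self._map_with_contacts(9, 30))

    def test_planted_bound_pose_detected_every_frame(self):
        params = pm.GeneratorParams(patch_nm=25.0, n_proteins=4, n_frames=6,
                                    seed=21, planted_bonds=[(0, 1, 1)])
        topo, f0 = pm.build_system(params)
        traj, truth = pm.simulate(topo, f0, params)
        for f in range(traj.n_frames):
            dimers = pm.detect_dimers(traj.positions[f], topo)
            assert any(d.pair == (0, 1) for d in dimers)


class TestNaming:
    def _system(self):
        params = pm.GeneratorParams(patch_nm=25.0, n_proteins=4, n_frames=1,
                                    seed=2)
        return pm.build_system(params)[0]

    def _named_map(self, topo, helix_residue_counts_1, helix_residue_counts_2):
        prot = topo.proteins[0]
        n = prot.n_residues
        D = np.zeros((n, n), dtype=np.uint8)
        col = 0
        for side, counts in ((0, helix_residue_counts_1),
                             (1, helix_residue_counts_2)):
            for hx, cnt in counts.items():
                lo, _ = prot.helix_map[hx]
                for k in range(cnt):
                    r = lo - 65 + k
                    if side == 0:
                        D[r, col % n] = 1
                        col += 1
                    else:
                        D[col % n, r] = 1
                        col += 1
        return D

    def test_three_residue_threshold_in_name(self):
        topo = self._system()
        prot = topo.proteins[0]
        n = prot.n_residues
        D = np.zeros((n, n), dtype=np.uint8)
        # side 1: TM1 x4, TM2 x3, H8 x5; side 2: TM4 x6 (+TM5 x2, below threshold)
        side1 = ([prot.helix_map["TM1"][0] - 65 + k for k in range(4)]
                 + [prot.helix_map["TM2"][0] - 65 + k for k in range(3)]
                 + [prot.helix_map["H8"][0] - 65 + k for k in range(5)])
        side2 = ([prot.helix_map["TM4"][0] - 65 + k for k in range(6)]
                 + [prot.helix_map["TM5"][0] - 65 + k for k in range(2)])
        for a in side1:
            D[a, side2[0]] = 1
        for b in side2:
            D[side1[0], b] = 1
        cm = ContactMap((0, 1), ("inactive", "inactive"), 0, D)
        name, flagged = pm.name_interface(cm, topo)
        assert name == "TM1,2,H8/TM4"
        assert not flagged

    def test_symmetric_map_gives_palindromic_name(self):
        params = pm.GeneratorParams(patch_nm=25.0, n_proteins=4, n_frames=1,
                                    seed=3, planted_bonds=[(0, 1, 0)])
        topo, f0 = pm.build_system(params)
        cm = pm.detect_dimers(f0.positions, topo)[0]
        name, _ = pm.name_interface(cm, topo)
        assert name == "TM1,2,H8/TM1,2,H8"

    def test_fallback_side_is_flagged(self):
        topo = self._system()
        prot = topo.proteins[0]
        n = prot.n_residues
        D = np.zeros((n, n), dtype=np.uint8)
        lo = prot.helix_map["TM3"][0] - 65
        D[lo, 0] = D[lo + 1, 0] = 1  # TM3 has only 2 contacting residues
        D[lo, 1] = 1
        cm = ContactMap((0, 1), ("inactive", "inactive"), 0, D)
        name, flagged = pm.name_interface(cm, topo)
        assert flagged


class TestClusteringMetric:
    def test_identical_maps_zero(self, rng):
        A = (rng.random((30, 30)) < 0.1).astype(float)
        assert map_dissimilarity(A, A.copy()) == 0.0

    def test_mismatch_count(self, rng):
        A = np.zeros((30, 30))
        B = A.copy()
        idx = rng.choice(900, size=17, replace=False)
        B.ravel()[idx] = 1
        assert map_dissimilarity(A, B) <= 17
        # symmetric A means no ordering gain: exactly the mismatch count
        assert map_dissimilarity(np.zeros((30, 30)), B) == min(
            17, 17)  # trivially the same both orderings

    def test_metric_axioms_on_random_binary_maps(self, rng):
        maps = [(rng.random((15, 15)) < 0.2).astype(float) for _ in range(12)]
        d = lambda a, b: np.sqrt(map_dissimilarity(a, b))
        for A in maps[:5]:
            for B in maps[:5]:
                assert d(A, B) == pytest.approx(d(B, A))
        for _ in range(60):
            i, j, k = rng.integers(0, len(maps), 3)
            assert d(maps[i], maps[k]) <= d(maps[i], maps[j]) + d(maps[j], maps[k]) + 1e-9


class TestClusterInterfaces:
    def test_planted_archetypes_recovered(self, rng):
        params = pm.GeneratorParams(patch_nm=25.0, n_proteins=4, n_frames=1, seed=2)
        topo, _ = pm.build_system(params)
        n = topo.proteins[0].n_residues
        archetypes = []
        for a in range(3):
            D = np.zeros((n, n))
            rows = rng.choice(n, size=30, replace=False)
            cols = rng.choice(n, size=30, replace=False)
            D[np.ix_(rows, cols)] = 1
            archetypes.append(D)
        maps, labels = [], []
        for k in range(60):
            a = k % 3
            D = archetypes[a].copy()
            noise = rng.random(D.shape) < 0.05
            D = np.abs(D - noise)
            maps.append(ContactMap((0, 1), ("inactive", "inactive"), k,
                                   D.astype(np.uint8)))
            labels.append(a)
        res = cluster_interfaces(maps, topo, k_range=range(2, 7), seed=0)
        assert adjusted_rand_score(labels, res.labels) >= 0.9

    def test_k_exceeding_sample_count_raises(self, rng):
        params = pm.GeneratorParams(patch_nm=25.0, n_proteins=4, n_frames=1, seed=2)
        topo, _ = pm.build_system(params)
        n = topo.proteins[0].n_residues
        maps = [ContactMap((0, 1), ("inactive", "inactive"), 0,
                           (rng.random((n, n)) < 0.05).astype(np.uint8))
                for _ in range(3)]
        with pytest.raises(ValueError):
            cluster_interfaces(maps, topo, k_range=range(5, 6))


class TestMonomers:
    def test_all_far_apart_counts_all(self):
        params = pm.GeneratorParams(patch_nm=50.0, n_proteins=16, n_frames=2,
                                    seed=6, d_protein_nm2_ns=0.0,
                                    d_rot_rad2_ns=0.0, interface_library=[])
        topo, f0 = pm.build_system(params)
        traj, _ = pm.simulate(topo, f0, params)
        per_rep, mean = pm.count_monomers(traj, topo)
        assert np.all(per_rep == 16)

    def test_planted_dimer_removes_two(self):
        params = pm.GeneratorParams(patch_nm=50.0, n_proteins=16, n_frames=2,
                                    seed=6, d_protein_nm2_ns=0.0,
                                    d_rot_rad2_ns=0.0, interface_library=[],
                                    planted_bonds=[(5, 6, 0)])
        params.interface_library = pm.default_interface_library()
        topo, f0 = pm.build_system(params)
        traj, _ = pm.simulate(topo, f0, params)
        per_rep, mean = pm.count_monomers(traj, topo)
        assert np.all(per_rep == 14)


class TestRmsd:
    def test_identical_dimers_zero(self, rng):
        P = rng.normal(size=(50, 3))
        assert pm.interface_rmsd(P, P.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        P = rng.normal(size=(50, 3))
        a = 0.7
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        Q = P @ R.T + np.array([1.0, -2.0, 0.5])
        assert pm.interface_rmsd(P, Q) == pytest.approx(0.0, abs=1e-9)

    def test_single_bead_displacement_hand_value(self):
        """One bead moved 0.1 nm out of 50: RMSD = sqrt(0.01/50) nm = 0.1414 A
        (least-squares superposition shrinks it slightly below that bound)."""
        rng = np.random.default_rng(14)
        P = rng.normal(size=(50, 3)) * 5
        Q = P.copy()
        Q[0] += [0.1, 0.0, 0.0]
        r = pm.interface_rmsd(P, Q)
        assert r <= np.sqrt(0.01 / 50) * 10 + 1e-9
        assert r == pytest.approx(0.1414, abs=0.01)

    def test_too_few_beads_raises(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestOligomers:
    def test_chain_of_two_dimers_is_a_trimer(self):
        oligs = detect_oligomers([(0, 1, "TM5/TM5"), (1, 2, "TM4/TM5")], 5)
        assert len(oligs) == 1
        assert oligs[0].members == [0, 1, 2]
        assert oligs[0].edge_names() == ["TM5_A/TM5_B", "TM4_B/TM5_C"]

    def test_no_edges_no_oligomers(self):
        assert detect_oligomers([], 5) == []

    def test_planted_linear_trimer_recovered(self):
        params = pm.GeneratorParams(
            patch_nm=30.0, n_proteins=5, n_frames=3, seed=13,
            planted_bonds=[(0, 1, 1), (1, 2, 0)])
        topo, f0 = pm.build_system(params)
        traj, truth = pm.simulate(topo, f0, params)
        dimers = pm.detect_dimers(traj.positions[-1], topo)
        edges = [(d.pair[0], d.pair[1], pm.name_interface(d, topo)[0])
                 for d in dimers]
        oligs = detect_oligomers(edges, 5)
        assert len(oligs) == 1
        assert oligs[0].members == [0, 1, 2]
        names = {(i, j): nm for i, j, nm in edges}
        assert names[(0, 1)] == "TM1,2,H8/TM5,6"
        assert names[(1, 2)] == "TM1,2,H8/TM1,2,H8"
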