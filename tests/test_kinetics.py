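import numpy as np
import pandas as pd
import pytest

import protomem as pm
from protomem.kinetics import dwell_lengths
from protomem.topology import SystemTopology, default_species
from protomem.trajectory import Trajectory


def chol_z_trajectory(z_paths, box=(10.0, 10.0, 11.0), balance=True):
    """CHOL molecules following prescribed z(t) for their ROH bead.

    A large static ballast of PC lipids pins the midplane at z = 0.
    """
    z_paths = np.atleast_2d(np.asarray(z_paths, dtype=float))
    n_mol, n_frames = z_paths.shape
    chol = default_species(1, "CHOL")
    pc = default_species(1, "PC")
    n_pc = 200
    species = [chol, pc]
    sp_idx = np.r_[np.zeros(n_mol, int), np.ones(n_pc, int)]
    leaflet = np.r_[np.ones(n_mol, int),
                    np.where(np.arange(n_pc) % 2 == 0, 1, -1)]
    first = np.empty(n_mol + n_pc, dtype=int)
    cursor = 0
    for i, si in enumerate(sp_idx):
        first[i] = cursor
        cursor += species[si].n_beads
    pos = np.zeros((n_frames, cursor, 3))
    rng = np.random.default_rng(0)
    pc_xy = rng.uniform(0, box[0], size=(n_pc, 2))
    for f in range(n_frames):
        for m in range(n_mol):
            sl = slice(first[m], first[m] + chol.n_beads)
            pos[f, sl, 0] = 1.0 + m
            pos[f, sl, 1] = 1.0
            pos[f, sl, 2] = z_paths[m, f]
            pos[f, first[m] + 3, 2] = z_paths[m, f] - 1.2  # tail end
        for k in range(n_pc):
            i = n_mol + k
            sl = slice(first[i], first[i] + pc.n_beads)
            pos[f, sl, :2] = pc_xy[k]
            pos[f, sl, 2] = 2.0 * leaflet[i]
    topo = SystemTopology(species=species, lipid_species_index=sp_idx,
                          lipid_leaflet=leaflet, lipid_first_bead=first,
                          proteins=[], box=np.array(box))
    traj = Trajectory(times=np.arange(n_frames, dtype=float), positions=pos,
                      box=np.array(box), topology=topo)
    return topo, traj


class TestDwell:
    def test_run_length_encoding(self):
        assert dwell_lengths([1, 1, 1, 0]).tolist() == [3]
        assert dwell_lengths([0, 0]).tolist() == []
        assert dwell_lengths([1, 0, 1, 0, 1]).tolist() == [1, 1, 1]
        assert dwell_lengths([1, 1]).tolist() == [2]

    def test_sum_of_dwells_equals_total_contact_frames(self, rng):
        x = rng.random(500) < 0.3
        assert dwell_lengths(x).sum() == x.sum()

    def test_dwell_intervals_against_planted_contacts(self):
        # one protomer; a CHOL parked within 1.2 nm of a TM6 sidechain bead
        # for frames 0-2, away for frame 3, back for frames 4-5
        from test_receptor import build_protein_system
        topo, traj = build_protein_system(lipid_xyz=[[0.0, 0.0, 0.0]], n_frames=6)
        prot = topo.proteins[0]
        sc_bead = traj.positions[0][prot.helix_sc_indices("TM6")[5]]
        near = sc_bead + [0.5, 0, 0]
        lip = slice(topo.lipid_first_bead[0], None)
        pos = traj.positions.copy()
        pos[:, lip, :] = near
        pos[3, lip, :2] = 1.0  # far corner
        traj2 = Trajectory(times=traj.times, positions=pos, box=traj.box,
                           topology=topo)
        summ = pm.dwell_intervals(traj2, topo, "CHOL", "TM6")
        assert sorted(summ.dwell_samples[0].tolist()) == [2.0, 3.0]
        assert summ.mean_ns == pytest.approx(2.5)

    def test_never_in_contact_is_flagged_undefined(self):
        from test_receptor import build_protein_system
        topo, traj = build_protein_system(lipid_xyz=[[18.0, 18.0, 2.0]], n_frames=3)
        summ = pm.dwell_intervals(traj, topo, "CHOL", "TM6")
        assert not summ.defined


class TestDetectFlips:
    def test_aborted_crossing_records_nothing(self):
        topo, traj = chol_z_trajectory([[1.5, 0.2, 1.4]])
        assert len(pm.detect_flips(traj, topo, "CHOL")) == 0

    def test_completed_crossing_records_one_event(self):
        topo, traj = chol_z_trajectory([[1.5, 0.2, -1.2]])
        ev = pm.detect_flips(traj, topo, "CHOL")
        assert len(ev) == 1
        assert ev.iloc[0]["direction"] == "up->down"
        assert ev.iloc[0]["frame"] == 2

    def test_middle_zone_dithering_is_hysteretic(self):
        topo, traj = chol_z_trajectory([[1.5, 0.5, -0.5, 0.5, -0.5, -1.2, 0.0, 1.3]])
        ev = pm.detect_flips(traj, topo, "CHOL")
        assert len(ev) == 2
        assert ev["direction"].tolist() == ["up->down", "down->up"]

    def test_count_is_time_reversal_symmetric(self, rng):
        z = np.clip(np.cumsum(rng.normal(0, 0.6, size=200)) + 1.5, -2.2, 2.2)
        topo1, traj1 = chol_z_trajectory([z])
        topo2, traj2 = chol_z_trajectory([z[::-1]])
        n1 = len(pm.detect_flips(traj1, topo1, "CHOL"))
        n2 = len(pm.detect_flips(traj2, topo2, "CHOL"))
        assert n1 == n2

    def test_non_flip_capable_species_rejected(self):
        topo, traj = chol_z_trajectory([[1.5, 1.5]])
        with pytest.raises(ValueError, match="flip-capable"):
            pm.detect_flips(traj, topo, "PC")


class TestFlipRate:
    def _fake_traj(self, n_mol, t_ns):
        topo, traj = chol_z_trajectory(np.full((n_mol, 2), 1.5),
                                       balance=True)
        traj = Trajectory(times=np.array([0.0, t_ns]),
                          positions=traj.positions, box=traj.box, topology=topo)
        return topo, traj

    def test_one_crossing_per_molecule_microsecond(self):
        topo, traj = self._fake_traj(1, 1000.0)  # 1 us observed
        ev = pd.DataFrame({"molecule": [0], "frame": [1], "direction": ["up->down"]})
        est = pm.flip_rate(ev, traj, topo, "CHOL")
        assert est.rate_per_s == pytest.approx(1e6)

    def test_zero_events_reports_bound(self):
        topo, traj = self._fake_traj(10, 1000.0)
        ev = pd.DataFrame(columns=["molecule", "frame", "direction"])
        est = pm.flip_rate(ev, traj, topo, "CHOL")
        assert est.rate_per_s == 0.0
        assert est.upper_bound_per_s == pytest.approx(3.0 / (10 * 1e-6))

    def test_zero_observation_time_raises(self):
        topo, traj = chol_z_trajectory([[1.5]])
        ev = pd.DataFrame(columns=["molecule", "frame", "direction"])
        with pytest.raises(ValueError, match="observation"):
            pm.flip_rate(ev, traj, topo, "CHOL")


class TestZMinDist:
    def test_histogram_sums_to_one_and_single_cell(self):
        from test_receptor import build_protein_system
        topo, traj = build_protein_system(lipid_xyz=[[14.0, 10.0, 1.2]], n_frames=3)
        H, ze, de = pm.z_mindist_density(traj, topo, "CHOL")
        assert H.sum() == pytest.approx(1.0)
        assert np.sum(H > 0) == 1

    def test_min_distance_matches_brute_force(self, rng):
        from test_receptor import build_protein_system
        xyz = np.c_[rng.uniform(4, 16, size=(20, 2)), rng.uniform(-2, 2, 20)]
        topo, traj = build_protein_system(lipid_xyz=xyz)
        d_edges = np.linspace(0, 15, 400)
        H, ze, de = pm.z_mindist_density(traj, topo, "CHOL",
                                         d_edges=d_edges)
        bb = topo.all_protein_bb_indices()
        refs = topo.reference_bead_indices(topo.lipids_of_class("CHOL"))
        pos = traj.positions[0]
        for r in refs:
            dmin = np.inf
            for b in bb:
                disp = pm.min_image_displacement(pos[r], pos[b], traj.box)
                dmin = min(dmin, np.linalg.norm(disp))
            di = np.searchsorted(d_edges, dmin, side="right") - 1
            assert H[:, di].sum() > 0


class TestFeaturize:
    def test_far_chol_has_zone_bit_only(self):
        from test_receptor import build_protein_system
        # symmetric pair keeps the instantaneous midplane at z = 0
        topo, traj = build_protein_system(
            lipid_xyz=[[18.0, 18.0, 1.2], [18.0, 16.0, -1.2]], n_frames=2)
        fp = pm.featurize_chol(traj, topo)
        n_res = topo.proteins[0].n_residues
        assert fp.shape == (2, 2, n_res + 3)
        assert fp[:, :, :n_res].sum() == 0
        assert fp[0, 0, n_res:].tolist() == [1, 0, 0]  # upper head zone
        assert fp[1, 0, n_res:].tolist() == [0, 0, 1]  # lower head zone

    def test_translation_invariance_in_xy(self):
        from test_receptor import build_protein_system
        topo, traj = build_protein_system(lipid_xyz=[[12.5, 10.0, 0.2]], n_frames=1)
        fp1 = pm.featurize_chol(traj, topo)
        pos = traj.positions.copy()
        pos[..., :2] = np.mod(pos[..., :2] + [7.3, 4.1], 20.0)
        traj2 = Trajectory(times=traj.times, positions=pos, box=traj.box,
                           topology=topo)
        fp2 = pm.featurize_chol(traj2, topo)
        assert np.array_equal(fp1[..., :-3], fp2[..., :-3])

    def test_contacts_match_brute_force(self, rng):
        from test_receptor import build_protein_system
        xyz = np.c_[rng.uniform(6, 14, size=(10, 2)), rng.uniform(-1.5, 1.5, 10)]
        topo, traj = build_protein_system(lipid_xyz=xyz)
        fp = pm.featurize_chol(traj, topo, cutoff=0.7)
        prot = topo.proteins[0]
        refs = topo.reference_bead_indices(topo.lipids_of_class("CHOL"))
        pos = traj.positions[0]
        for m, r in enumerate(refs):
            for res in range(prot.n_residues):
                disp = pm.min_image_displacement(pos[r], pos[prot.bb_index[res]],
                                                 traj.box)
                expected = np.linalg.norm(disp) <= 0.7
                assert bool(fp[m, 0, res]) == expected
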