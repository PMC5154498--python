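import numpy as np
import pytest

import protomem as pm
from protomem.generator import _protein_template
from protomem.receptor import (monomer_mask, protein_com, reference_angle,
                               wrap_angle)
from protomem.topology import ProteinTopology, SystemTopology, default_species
from protomem.trajectory import Trajectory


def build_protein_system(lipid_xyz=(), lipid_class="CHOL", box=(20.0, 20.0, 11.0),
                         center=(10.0, 10.0), theta=0.0, n_frames=1,
                         conformation="inactive"):
    """One template protomer plus explicitly placed lipids of one class."""
    bb_t, sc_t, resnum, hmap = _protein_template(conformation)
    n_res = len(resnum)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    shift = np.array([center[0], center[1], 0.0])
    prot_pos = np.concatenate([bb_t @ R.T + shift, sc_t @ R.T + shift])
    protein = ProteinTopology(
        protein_id=0, conformation=conformation, residue_numbers=resnum,
        bb_index=np.arange(n_res),
        sc_indices=[np.array([n_res + r]) for r in range(n_res)],
        helix_map=hmap)
    sp = default_species(1, lipid_class)
    lipid_xyz = np.atleast_2d(np.asarray(lipid_xyz, dtype=float)) \
        if len(lipid_xyz) else np.empty((0, 3))
    n_lip = len(lipid_xyz)
    lip_pos = np.repeat(lipid_xyz, sp.n_beads, axis=0)
    pos = np.concatenate([prot_pos, lip_pos])
    topo = SystemTopology(
        species=[sp], lipid_species_index=np.zeros(n_lip, dtype=int),
        lipid_leaflet=np.ones(n_lip, dtype=int),
        lipid_first_bead=2 * n_res + sp.n_beads * np.arange(n_lip),
        proteins=[protein], box=np.array(box))
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      positions=np.repeat(pos[None], n_frames, axis=0),
                      box=np.array(box), topology=topo)
    return topo, traj


class TestTilt:
    def test_vertical_bundle_has_zero_tilt_and_phi_zero(self):
        topo, traj = build_protein_system()
        rec = pm.protomer_tilt(traj.positions[0], topo.proteins[0], box=traj.box)
        assert rec.theta < np.deg2rad(2.0)

    def test_ten_degree_rotation_about_y(self):
        topo, traj = build_protein_system()
        pos = traj.positions[0].copy()
        prot = topo.proteins[0]
        idx = np.concatenate([prot.bb_index] + list(prot.sc_indices))
        com = pos[idx].mean(axis=0)
        a = np.deg2rad(10.0)
        R = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0],
                      [-np.sin(a), 0, np.cos(a)]])
        pos[idx] = (pos[idx] - com) @ R.T + com
        rec = pm.protomer_tilt(pos, prot, box=traj.box)
        assert rec.theta == pytest.approx(np.deg2rad(10.0), abs=np.deg2rad(2.0))

    def test_tilt_toward_tm1_gives_phi_zero(self):
        topo, traj = build_protein_system()
        pos = traj.positions[0].copy()
        prot = topo.proteins[0]
        th_ref = reference_angle(pos, prot, box=traj.box)
        # tip the axis toward the TM1 direction
        tilt_axis = np.array([-np.sin(th_ref), np.cos(th_ref), 0.0])
        a = np.deg2rad(12.0)
        K = np.array([[0, -tilt_axis[2], tilt_axis[1]],
                      [tilt_axis[2], 0, -tilt_axis[0]],
                      [-tilt_axis[1], tilt_axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K
        idx = np.concatenate([prot.bb_index] + list(prot.sc_indices))
        com = pos[idx].mean(axis=0)
        pos[idx] = (pos[idx] - com) @ R.T + com
        rec = pm.protomer_tilt(pos, prot, box=traj.box)
        assert abs(wrap_angle(rec.phi)) < np.deg2rad(10.0)

    def test_degenerate_covariance_raises(self):
        prot = ProteinTopology(0, "inactive", np.arange(65, 68), np.arange(3))
        pos = np.tile([[1.0, 1.0, 1.0]], (3, 1))
        with pytest.raises(ValueError, match="degenerate"):
            pm.protomer_tilt(pos, prot)


class TestDensityMap:
    def test_single_glued_lipid_single_bin(self):
        topo, traj = build_protein_system(lipid_xyz=[[13.0, 10.0, 2.0]], n_frames=3)
        fld = pm.density_map(traj, topo, "CHOL", 0, align=False)
        prob = fld.probability()
        assert prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.max(prob) == pytest.approx(1.0)

    def test_normalization_for_any_input(self, rng):
        xyz = np.c_[rng.uniform(6, 14, size=(200, 2)), np.full(200, 2.0)]
        topo, traj = build_protein_system(lipid_xyz=xyz)
        fld = pm.density_map(traj, topo, "CHOL", 0)
        assert fld.probability().sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sea_is_flat_within_multinomial_error(self, rng):
        n = 40_000
        xyz = np.c_[rng.uniform(0, 20, size=(n, 2)), np.full(n, 2.0)]
        topo, traj = build_protein_system(lipid_xyz=xyz)
        fld = pm.density_map(traj, topo, "CHOL", 0, align=False)
        M = fld.count.sum()
        p0 = 1.0 / (fld.shape[0] * fld.shape[1])
        sigma = np.sqrt(p0 * (1 - p0) / M)
        dev = np.abs(fld.probability() - p0)
        # per-bin 3-sigma check with a 1% allowance for multiple comparisons
        assert np.mean(dev > 3 * sigma) < 0.01

    def test_equivariance_under_90_degree_rotation(self, rng):
        xyz = np.c_[rng.uniform(5, 15, size=(300, 2)), np.full(300, 2.0)]
        topo, traj = build_protein_system(lipid_xyz=xyz)
        fld1 = pm.density_map(traj, topo, "CHOL", 0, align=True)
        # rotate the whole frame by 90 degrees about the box center
        c = np.array([10.0, 10.0, 0.0])
        pos = traj.positions[0] - c
        rot = np.stack([-pos[:, 1], pos[:, 0], pos[:, 2]], axis=1) + c
        traj2 = Trajectory(times=traj.times, positions=rot[None],
                           box=traj.box, topology=topo)
        fld2 = pm.density_map(traj2, topo, "CHOL", 0, align=True)
        assert np.allclose(fld1.probability(), fld2.probability())

    def test_no_qualifying_frames_raises(self):
        # two protomers 3 nm apart: never monomeric
        topo, traj = build_protein_system(lipid_xyz=[[13.0, 10.0, 2.0]])
        bb_t, sc_t, resnum, hmap = _protein_template("inactive")
        n_res = len(resnum)
        n0 = traj.positions.shape[1]
        extra = np.concatenate([bb_t, sc_t]) + np.array([13.0, 10.0, 0.0])
        pos = np.concatenate([traj.positions[0], extra])
        topo.proteins.append(ProteinTopology(
            protein_id=1, conformation="inactive", residue_numbers=resnum,
            bb_index=n0 + np.arange(n_res),
            sc_indices=[np.array([n0 + n_res + r]) for r in range(n_res)],
            helix_map=hmap))
        traj2 = Trajectory(times=np.array([0.0]), positions=pos[None],
                           box=traj.box, topology=topo)
        with pytest.raises(ValueError, match="monomeric"):
            pm.density_map(traj2, topo, "CHOL", 0)


class TestResidueContacts:
    def _system_with_lipid_near(self, residue_index, offset=0.5, n_frames=4):
        topo, traj = build_protein_system(n_frames=n_frames)
        prot = topo.proteins[0]
        bead = traj.positions[0][prot.bb_index[residue_index]]
        xyz = bead + np.array([offset, 0, 0])
        return build_protein_system(lipid_xyz=[xyz], n_frames=n_frames)

    def test_glued_lipid_probability_one(self):
        topo, traj = self._system_with_lipid_near(10, offset=0.3)
        table = pm.residue_contact_probability(traj, topo)
        assert table["contact_probability"].iloc[10] == 1.0

    def test_distant_lipid_probability_zero(self):
        topo, traj = build_protein_system(lipid_xyz=[[18.0, 18.0, 2.0]], n_frames=4)
        table = pm.residue_contact_probability(traj, topo)
        assert (table["contact_probability"] == 0).all()

    def test_half_frames_gives_half(self):
        topo, traj = self._system_with_lipid_near(10, offset=0.3, n_frames=4)
        lip_beads = slice(topo.lipid_first_bead[0], None)
        pos = traj.positions.copy()
        pos[2:, lip_beads, :2] = 18.0  # move away for the last two frames
        traj2 = Trajectory(times=traj.times, positions=pos, box=traj.box,
                           topology=topo)
        table = pm.residue_contact_probability(traj2, topo)
        assert table["contact_probability"].iloc[10] == pytest.approx(0.5)


class TestHelixAzimuthProfile:
    def test_planted_tm5_order_bias_minimizes_chi_at_tm5(self):
        params = pm.GeneratorParams(
            patch_nm=16.0, n_proteins=1, n_frames=50, seed=9,
            d_protein_nm2_ns=0.0, d_rot_rad2_ns=0.0,
            helix_order_bias={"TM5": -0.20}, sm_coupling=0.0,
            background_order_sd=0.0,
            flip_rates_per_s={"CHOL": 0.0}, store_chi=False)
        topo, f0 = pm.build_system(params)
        traj, _ = pm.simulate(topo, f0, params)
        prof = pm.helix_azimuth_profile(traj, topo, bin_deg=15.0)
        i_min = np.nanargmin(prof.order_mean)
        az_min = prof.azimuth_centers[i_min]
        assert abs(wrap_angle(az_min - prof.helix_marks["TM5"])) < np.deg2rad(40.0)

    def test_unbiased_field_profile_is_flat(self):
        params = pm.GeneratorParams(
            patch_nm=16.0, n_proteins=1, n_frames=200, seed=10,
            d_protein_nm2_ns=0.0, d_rot_rad2_ns=0.0,
            helix_order_bias={}, sm_coupling=0.0, background_order_sd=0.0,
            flip_rates_per_s={"CHOL": 0.0}, store_chi=False)
        topo, f0 = pm.build_system(params)
        traj, _ = pm.simulate(topo, f0, params)
        prof = pm.helix_azimuth_profile(traj, topo, bin_deg=20.0)
        spread = np.nanmax(prof.order_mean) - np.nanmin(prof.order_mean)
        assert spread < 0.08


class TestMonomerMask:
    def test_boundary_at_exactly_5_nm_is_monomeric(self):
        coms = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])
        mask = monomer_mask(coms, np.array([50.0, 50.0, 11.0]))
        assert mask.all()

    def test_below_5_nm_is_not(self):
        coms = np.array([[[0.0, 0, 0], [4.9, 0, 0]]])
        mask = monomer_mask(coms, np.array([50.0, 50.0, 11.0]))
        assert not mask.any()
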