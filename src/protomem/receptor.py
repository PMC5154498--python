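"""Receptor-centered analyses: lipid density maps, per-residue lipid contact
probabilities, helix-azimuth order/thickness profiles, and protomer tilt.

All receptor-frame analyses share one convention: the protein's internal
reference direction is the xy projection of the vector from the protein center
of mass (COM) to the COM of helix TM1.  Density maps are rotated so this
direction points along +x, and azimuths/tilt direction phi are measured from
it.  The COM uses backbone beads only by default (configurable); beads are
treated as equal mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fields import DENSITY_BIN_NM, DENSITY_N_BINS, ScalarField2D
from .geometry import center_of_mass, min_image_displacement, unwrap_about
from .order import lipid_order_samples
from .trajectory import bilayer_midplane

#: Lateral cutoff (nm) for the helix-azimuth profiles.
AZIMUTH_PROFILE_RCUT = 3.125
#: COM separation (nm) at or above which a receptor counts as monomeric.
MONOMER_MIN_DISTANCE = 5.0
#: Default lipid-residue contact cutoff (nm) for contact-probability maps.
LIPID_CONTACT_CUTOFF = 0.7


def protein_com(positions, protein, box=None, backbone_only: bool = True) -> np.ndarray:
    """Center of mass of one protomer (equal-mass beads, unwrap-aware)."""
    idx = protein.bb_index
    if not backbone_only and protein.sc_indices:
        idx = np.concatenate([idx] + list(protein.sc_indices))
    return center_of_mass(positions[idx], box=box)


def helix_com(positions, protein, helix: str, box=None) -> np.ndarray:
    return center_of_mass(positions[protein.helix_bb_indices(helix)], box=box)


def reference_angle(positions, protein, box=None) -> float:
    """Lab-frame angle of the COM -> TM1-COM xy projection (radians)."""
    com = protein_com(positions, protein, box=box)
    tm1 = helix_com(positions, protein, "TM1", box=box)
    d = min_image_displacement(com, tm1, box) if box is not None else tm1 - com
    return float(np.arctan2(d[1], d[0]))


def wrap_angle(a) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(np.isclose(out, -np.pi), np.pi, out)


def protein_coms(traj, topology, backbone_only: bool = True) -> np.ndarray:
    """(n_frames, n_proteins, 3) protomer COMs."""
    out = np.empty((traj.n_frames, len(topology.proteins), 3))
    for i in range(traj.n_frames):
        for j, p in enumerate(topology.proteins):
            out[i, j] = protein_com(traj.positions[i], p, box=traj.box,
                                    backbone_only=backbone_only)
    return out


def monomer_mask(coms, box, min_distance: float = MONOMER_MIN_DISTANCE) -> np.ndarray:
    """(n_frames, n_proteins) True where a protomer is >= 5 nm from all others."""
    n_f, n_p = coms.shape[:2]
    mask = np.ones((n_f, n_p), dtype=bool)
    for i in range(n_f):
        d = np.linalg.norm(
            min_image_displacement(coms[i][:, None, :], coms[i][None, :, :], box),
            axis=-1)
        np.fill_diagonal(d, np.inf)
        mask[i] = d.min(axis=1) >= min_distance
    return mask


def density_map(traj, topology, headgroup_class: str, protein_id: int,
                n_bins: int = DENSITY_N_BINS, bin_size: float = DENSITY_BIN_NM,
                monomer_only: bool = True, align: bool = True) -> ScalarField2D:
    """Receptor-centered normalized 2D density of a lipid class.

    Reference beads of the class are binned into an ``n_bins x n_bins`` grid
    of ``bin_size`` nm centered on the protomer COM.  With ``align=True`` each
    frame is rotated so the COM->TM1 projection points along +x.  For free
    receptors only frames where the protomer is monomeric (COM >= 5 nm from
    every other protein) are used.
    """
    protein = topology.proteins[protein_id]
    ids = topology.lipids_of_class(headgroup_class)
    refs = topology.reference_bead_indices(ids)
    grid = ScalarField2D.centered(n_bins, bin_size)
    coms = protein_coms(traj, topology) if monomer_only else None
    mono = (monomer_mask(coms, traj.box)[:, protein_id] if monomer_only
            else np.ones(traj.n_frames, dtype=bool))
    n_used = 0
    for i in range(traj.n_frames):
        if not mono[i]:
            continue
        pos = traj.positions[i]
        com = protein_com(pos, protein, box=traj.box)
        disp = min_image_displacement(com, pos[refs], traj.box)[:, :2]
        if align:
            th = reference_angle(pos, protein, box=traj.box)
            c, s = np.cos(-th), np.sin(-th)
            disp = disp @ np.array([[c, -s], [s, c]]).T
        # clip to the grid footprint: a centered map must not wrap distant lipids
        half = n_bins * bin_size / 2.0
        inside = np.all(np.abs(disp) < half, axis=1)
        grid.add(disp[inside])
        n_used += 1
    if n_used == 0:
        raise ValueError("no qualifying (monomeric) frames for the density map")
    return grid


def residue_contact_probability(traj, topology, lipid_class: str = "CHOL",
                                cutoff: float = LIPID_CONTACT_CUTOFF,
                                protein_ids=None) -> pd.DataFrame:
    """Per-residue probability of contact with a lipid's reference bead.

    For each residue the fraction of protein-frames in which any reference
    bead of ``lipid_class`` (the ROH bead for CHOL) lies within ``cutoff`` of
    any of the residue's beads (BB + SC).  Pooled over the listed protomers.
    """
    if protein_ids is None:
        protein_ids = range(len(topology.proteins))
    protein_ids = list(protein_ids)
    lip = topology.reference_bead_indices(topology.lipids_of_class(lipid_class))
    if len(lip) == 0:
        raise ValueError(f"no lipids of class {lipid_class!r}")
    p0 = topology.proteins[protein_ids[0]]
    n_res = p0.n_residues
    hits = np.zeros(n_res)
    total = 0
    shifts = np.array([[i, j, 0.0] for i in (-1, 0, 1) for j in (-1, 0, 1)])
    for i in range(traj.n_frames):
        pos = traj.positions[i]
        images = (pos[lip][None, :, :] + shifts[:, None, :] *
                  np.array([traj.box[0], traj.box[1], 1.0])).reshape(-1, 3)
        tree = cKDTree(images)
        for pid in protein_ids:
            p = topology.proteins[pid]
            for r in range(n_res):
                beads = [p.bb_index[r]]
                if p.sc_indices:
                    beads.extend(p.sc_indices[r].tolist())
                d, _ = tree.query(pos[beads], k=1)
                if np.min(d) <= cutoff:
                    hits[r] += 1
            total += 1
    out = pd.DataFrame({
        "residue": p0.residue_numbers,
        "bw_label": [p0.bw_labels.get(int(r), "") for r in p0.residue_numbers],
        "contact_probability": hits / max(total, 1),
    })
    return out


@dataclass
class HelixAzimuthProfile:
    azimuth_centers: np.ndarray          # radians, receptor frame, (-pi, pi]
    order_mean: np.ndarray
    order_se: np.ndarray
    thickness_mean: np.ndarray
    thickness_se: np.ndarray
    helix_marks: dict[str, float]        # helix -> azimuth of its COM
    n_replicas: int


def _azimuth_profile_one(traj, topology, protein_ids, r_cut, edges):
    n_bins = len(edges) - 1
    order_sum = np.zeros(n_bins)
    order_n = np.zeros(n_bins)
    up_sum = np.zeros(n_bins); up_n = np.zeros(n_bins)
    lo_sum = np.zeros(n_bins); lo_n = np.zeros(n_bins)
    ids = topology.non_flipping_lipids()
    refs = topology.reference_bead_indices(ids)
    for i in range(traj.n_frames):
        pos = traj.positions[i]
        mid = bilayer_midplane(topology, pos)
        samples = lipid_order_samples(pos, topology, frame_index=i)
        for pid in protein_ids:
            p = topology.proteins[pid]
            com = protein_com(pos, p, box=traj.box)
            th = reference_angle(pos, p, box=traj.box)
            # order samples near this protomer
            d = min_image_displacement(com[:2].tolist() + [0.0],
                                       np.c_[samples.xy, np.zeros(len(samples))],
                                       traj.box)[:, :2]
            r = np.linalg.norm(d, axis=1)
            near = r <= r_cut
            az = wrap_angle(np.arctan2(d[near, 1], d[near, 0]) - th)
            bi = np.clip(np.searchsorted(edges, az, side="right") - 1, 0, n_bins - 1)
            np.add.at(order_sum, bi, samples.chi[near])
            np.add.at(order_n, bi, 1.0)
            # leaflet linker z for local thickness
            dl = min_image_displacement(com, pos[refs], traj.box)
            rl = np.linalg.norm(dl[:, :2], axis=1)
            nearl = rl <= r_cut
            azl = wrap_angle(np.arctan2(dl[nearl, 1], dl[nearl, 0]) - th)
            bil = np.clip(np.searchsorted(edges, azl, side="right") - 1, 0, n_bins - 1)
            z = pos[refs[nearl], 2]
            upper = z >= mid
            np.add.at(up_sum, bil[upper], z[upper]); np.add.at(up_n, bil[upper], 1.0)
            np.add.at(lo_sum, bil[~upper], z[~upper]); np.add.at(lo_n, bil[~upper], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        order = np.where(order_n > 0, order_sum / order_n, np.nan)
        thick = np.where((up_n > 0) & (lo_n > 0),
                         up_sum / np.maximum(up_n, 1) - lo_sum / np.maximum(lo_n, 1),
                         np.nan)
    return order, thick


def helix_azimuth_profile(trajs, topology, r_cut: float = AZIMUTH_PROFILE_RCUT,
                          bin_deg: float = 5.0, protein_ids=None
                          ) -> HelixAzimuthProfile:
    """Order/thickness vs azimuth around the protomer COM, with helix marks.

    Lipids whose reference bead lies laterally within ``r_cut`` of a protomer
    COM are binned by azimuth measured in the receptor frame (zero at the
    COM->TM1 direction).  ``trajs`` is a list of replicas; the profile is the
    replica mean with its standard error (n-1 denominator).  The x-axis is
    geometric azimuth; the helix COM azimuths are returned as tick marks.
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    if protein_ids is None:
        protein_ids = range(len(topology.proteins))
    protein_ids = list(protein_ids)
    n_bins = int(round(360.0 / bin_deg))
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    per_rep = [_azimuth_profile_one(t, topology, protein_ids, r_cut, edges)
               for t in trajs]
    orders = np.stack([o for o, _ in per_rep])
    thicks = np.stack([t for _, t in per_rep])
    R = len(trajs)
    se = lambda a: (np.nanstd(a, axis=0, ddof=1) / np.sqrt(R) if R > 1
                    else np.zeros(a.shape[1]))
    # helix marks from the first frame of the first replica
    pos0 = trajs[0].positions[0]
    marks = {}
    for hx in topology.proteins[protein_ids[0]].helix_map:
        p = topology.proteins[protein_ids[0]]
        com = protein_com(pos0, p, box=trajs[0].box)
        th = reference_angle(pos0, p, box=trajs[0].box)
        hc = helix_com(pos0, p, hx, box=trajs[0].box)
        d = min_image_displacement(com, hc, trajs[0].box)
        marks[hx] = float(wrap_angle(np.arctan2(d[1], d[0]) - th))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN azimuth bins
        return HelixAzimuthProfile(
            azimuth_centers=(edges[:-1] + edges[1:]) / 2,
            order_mean=np.nanmean(orders, axis=0), order_se=se(orders),
            thickness_mean=np.nanmean(thicks, axis=0), thickness_se=se(thicks),
            helix_marks=marks, n_replicas=R,
        )


@dataclass
class TiltRecord:
    protein_id: int
    frame: int
    theta: float   # tilt of the principal axis from the membrane normal, [0, pi/2]
    phi: float     # azimuth of the tilt w.r.t. the COM->TM1 projection, (-pi, pi]


def protomer_tilt(positions, protein, box=None, frame_index: int = 0) -> TiltRecord:
    """Tilt (theta) and tilt direction (phi) of a protomer's principal axis.

    The principal axis is the dominant eigenvector of the backbone-bead
    position covariance, oriented extracellular-up (+z); the covariance is
    taken over the transmembrane bundle (TM1-TM7) so loops, termini and the
    in-plane H8 do not skew the axis.  theta is its angle from the membrane
    normal; phi the signed angle between its xy projection and the COM->TM1
    projection.  For an untilted bundle phi is undefined and reported as 0.
    """
    tm = [hx for hx in protein.helix_map if hx.startswith("TM")]
    if tm:
        idx = np.concatenate([protein.helix_bb_indices(hx) for hx in tm])
    else:
        idx = protein.bb_index
    bb = positions[idx]
    if len(bb) < 3:
        raise ValueError("tilt needs at least 3 backbone beads")
    if box is not None:
        bb = unwrap_about(bb, bb[0], box)
    centered = bb - bb.mean(axis=0)
    cov = centered.T @ centered / len(bb)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12:
        raise ValueError("degenerate backbone covariance")
    axis = evecs[:, -1]
    if axis[2] < 0:
        axis = -axis
    theta = float(np.arccos(np.clip(axis[2], -1.0, 1.0)))
    proj = axis[:2]
    if np.linalg.norm(proj) < 1e-9:
        phi = 0.0
    else:
        th_ref = reference_angle(positions, protein, box=box)
        phi = float(wrap_angle(np.arctan2(proj[1], proj[0]) - th_ref))
    return TiltRecord(protein.protein_id, frame_index, theta, phi)
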