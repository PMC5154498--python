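"""Lipid kinetics: helix residence times, flip-flop detection and rates, and
z-vs-distance densities.

Flip-flop detection uses a three-zone scheme derived from the bilayer middle
being 1.6 nm thick: upper headgroup region (z > +0.8 nm from the midplane),
middle (|z| < 0.8 nm) and lower headgroup region.  An event is committed only
when a molecule reaches the head zone opposite its last committed one;
excursions into the middle that return do not count (hysteresis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .order import MIDDLE_ZONE_HALF_WIDTH
from .trajectory import bilayer_midplane

RESIDENCE_CUTOFF = 1.2  #: nm, lipid-to-helix-sidechain contact cutoff


def _tiled_tree(points: np.ndarray, box) -> cKDTree:
    """KD-tree over the 3x3 xy periodic images of ``points``."""
    shifts = np.array([[i, j, 0.0] for i in (-1, 0, 1) for j in (-1, 0, 1)])
    images = (points[None, :, :] + shifts[:, None, :] *
              np.array([box[0], box[1], 1.0])).reshape(-1, 3)
    return cKDTree(images)


def zone_series(traj, topology, lipid_ids) -> np.ndarray:
    """(n_frames, n_lipids) zone codes: +1 upper head, 0 middle, -1 lower head."""
    refs = topology.reference_bead_indices(lipid_ids)
    out = np.empty((traj.n_frames, len(refs)), dtype=np.int8)
    for i in range(traj.n_frames):
        z = traj.positions[i][refs, 2] - bilayer_midplane(topology, traj.positions[i])
        out[i] = np.where(np.abs(z) < MIDDLE_ZONE_HALF_WIDTH, 0,
                          np.where(z > 0, 1, -1))
    return out


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------

@dataclass
class ResidenceSummary:
    species: str
    helix: str
    dwell_samples: list[np.ndarray]  # per replica, ns
    mean_ns: float                   # NaN when no dwell was observed
    std_ns: float                    # over replicas

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean_ns)


def contact_series(traj, topology, lipid_ids, helix: str,
                   cutoff: float = RESIDENCE_CUTOFF) -> np.ndarray:
    """(n_frames, n_lipids) bool: reference bead within cutoff of any SC bead
    of ``helix`` on any protomer."""
    refs = topology.reference_bead_indices(lipid_ids)
    sc = [topology.proteins[p].helix_sc_indices(helix)
          for p in range(len(topology.proteins))]
    sc = np.concatenate([s for s in sc if len(s)]) if sc else np.empty(0, int)
    if len(sc) == 0:
        raise ValueError(f"helix {helix} has no sidechain beads")
    out = np.zeros((traj.n_frames, len(refs)), dtype=bool)
    for i in range(traj.n_frames):
        tree = _tiled_tree(traj.positions[i][sc], traj.box)
        d, _ = tree.query(traj.positions[i][refs], k=1)
        out[i] = d <= cutoff
    return out


def dwell_lengths(in_contact: np.ndarray) -> np.ndarray:
    """Lengths (frames) of maximal runs of True in a 1D bool series."""
    x = np.asarray(in_contact, dtype=bool).astype(int)
    if x.size == 0:
        return np.empty(0, dtype=int)
    padded = np.r_[0, x, 0]
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return ends - starts


def dwell_intervals(trajs, topology, species_class: str, helix: str,
                    cutoff: float = RESIDENCE_CUTOFF) -> ResidenceSummary:
    """Residence-time distribution of one lipid class at one helix.

    A dwell is a maximal run of consecutive frames in contact (a single
    out-frame ends it); its length is run length x frame stride (ns).  The
    summary mean/std follow the replica-averaging convention: the mean of the
    per-replica distributions and the spread across replicas.
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    ids = topology.lipids_of_class(species_class)
    per_rep = []
    for t in trajs:
        ic = contact_series(t, topology, ids, helix, cutoff)
        stride = t.stride if t.stride > 0 else 1.0
        runs = [dwell_lengths(ic[:, m]) for m in range(ic.shape[1])]
        per_rep.append(np.concatenate(runs).astype(float) * stride
                       if runs else np.empty(0))
    means = [s.mean() for s in per_rep if len(s)]
    mean = float(np.mean(means)) if means else float("nan")
    std = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return ResidenceSummary(species_class, helix, per_rep, mean, std)


# ---------------------------------------------------------------------------
# flip-flop
# ---------------------------------------------------------------------------

def detect_flips(traj, topology, species_class: str) -> pd.DataFrame:
    """Leaflet-crossing events of a flip-capable lipid class.

    Returns a table (molecule, frame, direction) where direction is
    ``up->down`` or ``down->up``; the event frame is the first frame the
    molecule enters the head zone opposite its last committed one.
    """
    ids = topology.lipids_of_class(species_class)
    if len(ids) and not topology.species[topology.lipid_species_index[ids[0]]].flip_capable:
        raise ValueError(f"{species_class} is not flip-capable")
    zones = zone_series(traj, topology, ids)
    rows = []
    for m in range(zones.shape[1]):
        z = zones[:, m]
        nz = np.nonzero(z)[0]
        if len(nz) == 0:
            continue
        committed = z[nz[0]]
        for f in nz:
            if z[f] == -committed:
                rows.append((int(ids[m]), int(f),
                             "up->down" if committed == 1 else "down->up"))
                committed = z[f]
    return pd.DataFrame(rows, columns=["molecule", "frame", "direction"])


@dataclass
class FlipRateEstimate:
    species: str
    counts: list[int]                 # per replica
    molecule_seconds: list[float]     # per replica: N_molecules x T_observed
    rate_per_s: float                 # mean of per-replica rates
    se_per_s: float                   # standard error over replicas
    upper_bound_per_s: float | None = None  # one-sided 95% bound when 0 events


def flip_rate(event_tables, trajs, topology, species_class: str) -> FlipRateEstimate:
    """Flip rate in events per molecule-second, mean +/- SE over replicas.

    Per replica: rate = n_events / (N_molecules x T_observed), with simulation
    time used as-is (no coarse-grained time rescaling).  With zero events the
    rate is 0 and a one-sided 95% Poisson bound (3/denominator) is attached.
    """
    if not isinstance(event_tables, (list, tuple)):
        event_tables = [event_tables]
        trajs = [trajs]
    n_mol = len(topology.lipids_of_class(species_class))
    counts, denoms, rates = [], [], []
    for ev, t in zip(event_tables, trajs):
        T_s = (t.times[-1] - t.times[0]) * 1e-9
        if T_s <= 0 or n_mol == 0:
            raise ValueError("zero observation time or no molecules")
        counts.append(int(len(ev)))
        denoms.append(n_mol * T_s)
        rates.append(len(ev) / (n_mol * T_s))
    rate = float(np.mean(rates))
    se = float(np.std(rates, ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else \
        float(np.sqrt(max(sum(counts), 1)) / sum(denoms))
    ub = 3.0 / sum(denoms) if sum(counts) == 0 else None
    return FlipRateEstimate(species_class, counts, denoms, rate, se, ub)


# ---------------------------------------------------------------------------
# z vs distance densities and cholesterol fingerprints
# ---------------------------------------------------------------------------

def z_mindist_density(traj, topology, species_class: str,
                      z_edges=None, d_edges=None):
    """Normalized 2D histogram of (z above midplane, min distance to protein BB).

    The z coordinate is that of the class's reference bead (ROH for CHOL, the
    AM1/GL1 linker for CER/DAG).  Returns (H, z_edges, d_edges) with H summing
    to 1.
    """
    z_edges = np.linspace(-2.5, 2.5, 51) if z_edges is None else np.asarray(z_edges)
    d_edges = np.linspace(0.0, 6.0, 61) if d_edges is None else np.asarray(d_edges)
    refs = topology.reference_bead_indices(topology.lipids_of_class(species_class))
    bb = topology.all_protein_bb_indices()
    if len(bb) == 0:
        raise ValueError("no protein backbone beads")
    H = np.zeros((len(z_edges) - 1, len(d_edges) - 1))
    for i in range(traj.n_frames):
        pos = traj.positions[i]
        tree = _tiled_tree(pos[bb], traj.box)
        d, _ = tree.query(pos[refs], k=1)
        z = pos[refs, 2] - bilayer_midplane(topology, pos)
        h, _, _ = np.histogram2d(z, d, bins=(z_edges, d_edges))
        H += h
    if H.sum() > 0:
        H /= H.sum()
    return H, z_edges, d_edges


def featurize_chol(traj, topology, cutoff: float = 0.7) -> np.ndarray:
    """Per-CHOL per-frame fingerprints for the kinetic model.

    Each fingerprint is a binary residue-contact vector (ROH within ``cutoff``
    of the BB bead of residue r on any protomer) concatenated with a one-hot
    z-zone indicator (upper head / middle / lower head).  Shape:
    (n_chol, n_frames, n_residues + 3), dtype uint8.
    """
    ids = topology.lipids_of_class("CHOL")
    refs = topology.reference_bead_indices(ids)
    n_res = topology.proteins[0].n_residues if topology.proteins else 0
    bb = topology.all_protein_bb_indices()
    zones = zone_series(traj, topology, ids)
    out = np.zeros((len(ids), traj.n_frames, n_res + 3), dtype=np.uint8)
    for f in range(traj.n_frames):
        if n_res:
            pos = traj.positions[f]
            tree = _tiled_tree(pos[bb], traj.box)
            neighbors = tree.query_ball_point(pos[refs], r=cutoff)
            n_img = len(bb)
            for m, hits in enumerate(neighbors):
                if hits:
                    res = np.unique(np.asarray(hits) % n_img) % n_res
                    out[m, f, res] = 1
        out[np.arange(len(ids)), f, n_res + (1 - zones[f].astype(int))] = 1  # +1->0, 0->1, -1->2
    return out
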