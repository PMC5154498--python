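"""Dimer-interface detection, naming, clustering, oligomers, and RMSD.

A residue-residue contact is two backbone beads within 0.8 nm; a dimer is a
protomer pair with at least ten contacting residues on *each* side; an
interface name lists, per side, the helices contributing three or more
contacting residues (in TM1..TM7, H8 order), sides joined by "/".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .geometry import min_image_displacement
from .receptor import MONOMER_MIN_DISTANCE, monomer_mask, protein_coms

CONTACT_CUTOFF = 0.8       #: nm, BB-BB contact distance
MIN_CONTACT_RESIDUES = 10  #: per side, for a dimer to count
MIN_HELIX_RESIDUES = 3     #: contacting residues for a helix to be named

HELIX_ORDER = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8")


@dataclass
class ContactMap:
    pair: tuple[int, int]
    conformations: tuple[str, str]
    frame: int
    D: np.ndarray  # binary (n_res_1, n_res_2)

    @property
    def side1_contacts(self) -> np.ndarray:
        return np.nonzero(self.D.any(axis=1))[0]

    @property
    def side2_contacts(self) -> np.ndarray:
        return np.nonzero(self.D.any(axis=0))[0]

    def transposed(self) -> "ContactMap":
        return ContactMap((self.pair[1], self.pair[0]),
                          (self.conformations[1], self.conformations[0]),
                          self.frame, self.D.T.copy())


def contact_map(positions, topology, i: int, j: int,
                cutoff: float = CONTACT_CUTOFF, frame: int = 0) -> ContactMap:
    """Binary residue-contact matrix between protomers i and j (min-image)."""
    pi_, pj = topology.proteins[i], topology.proteins[j]
    a = positions[pi_.bb_index]
    b = positions[pj.bb_index]
    d = np.linalg.norm(
        min_image_displacement(a[:, None, :], b[None, :, :], topology.box), axis=-1)
    return ContactMap((i, j), (pi_.conformation, pj.conformation), frame,
                      (d <= cutoff).astype(np.uint8))


def is_dimer(cmap: ContactMap, min_residues: int = MIN_CONTACT_RESIDUES) -> bool:
    return (len(cmap.side1_contacts) >= min_residues
            and len(cmap.side2_contacts) >= min_residues)


def detect_dimers(positions, topology, cutoff: float = CONTACT_CUTOFF,
                  frame: int = 0, max_com_distance: float = 8.0
                  ) -> list[ContactMap]:
    """Contact maps of all pairs qualifying as dimers in one frame.

    Pairs with COMs farther than ``max_com_distance`` are skipped without
    computing the full residue matrix (they cannot reach 0.8 nm contacts).
    """
    from .receptor import protein_com
    coms = [protein_com(positions, p, box=topology.box) for p in topology.proteins]
    out = []
    n = len(topology.proteins)
    for i in range(n):
        for j in range(i + 1, n):
            dc = np.linalg.norm(
                min_image_displacement(coms[i], coms[j], topology.box))
            if dc > max_com_distance:
                continue
            cm = contact_map(positions, topology, i, j, cutoff, frame)
            if is_dimer(cm):
                out.append(cm)
    return out


def _side_helix_counts(residue_ids, protein) -> dict[str, int]:
    counts = {}
    for hx in protein.helix_map:
        mask = protein.helix_residue_mask(hx)
        counts[hx] = int(np.sum(mask[residue_ids]))
    return counts


def _side_name(counts: dict[str, int]) -> tuple[str, bool]:
    named = [h for h in HELIX_ORDER if counts.get(h, 0) >= MIN_HELIX_RESIDUES]
    flagged = False
    if not named:
        # fall back to the single largest-contact helix, flagged
        best = max((h for h in counts), key=lambda h: counts[h], default=None)
        named = [best] if best and counts[best] > 0 else []
        flagged = True
    tm = [h[2:] for h in named if h.startswith("TM")]
    parts = []
    if tm:
        parts.append("TM" + ",".join(tm))
    if "H8" in named:
        parts.append("H8")
    return ",".join(parts) if parts else "none", flagged


def _lowest_helix_rank(counts: dict[str, int]) -> int:
    for rank, h in enumerate(HELIX_ORDER):
        if counts.get(h, 0) >= MIN_HELIX_RESIDUES:
            return rank
    for rank, h in enumerate(HELIX_ORDER):
        if counts.get(h, 0) > 0:
            return rank
    return len(HELIX_ORDER)


def canonicalize(cmap: ContactMap, topology) -> ContactMap:
    """Canonical side order: the side whose lowest-index contacting helix is
    smaller goes first; ties broken by conformation (inactive first), then by
    protomer id."""
    p1 = topology.proteins[cmap.pair[0]]
    p2 = topology.proteins[cmap.pair[1]]
    c1 = _side_helix_counts(cmap.side1_contacts, p1)
    c2 = _side_helix_counts(cmap.side2_contacts, p2)
    key1 = (_lowest_helix_rank(c1), 0 if cmap.conformations[0] == "inactive" else 1,
            cmap.pair[0])
    key2 = (_lowest_helix_rank(c2), 0 if cmap.conformations[1] == "inactive" else 1,
            cmap.pair[1])
    return cmap if key1 <= key2 else cmap.transposed()


def name_interface(cmap: ContactMap, topology, canonical: bool = True
                   ) -> tuple[str, bool]:
    """Interface name like "TM1,2,H8/TM4"; the flag marks a side that needed
    the largest-contact fallback (no helix reached 3 residues)."""
    if canonical:
        cmap = canonicalize(cmap, topology)
    p1 = topology.proteins[cmap.pair[0]]
    p2 = topology.proteins[cmap.pair[1]]
    n1, f1 = _side_name(_side_helix_counts(cmap.side1_contacts, p1))
    n2, f2 = _side_name(_side_helix_counts(cmap.side2_contacts, p2))
    return f"{n1}/{n2}", (f1 or f2)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def map_dissimilarity(A: np.ndarray, B: np.ndarray) -> float:
    """Tr(Delta^T Delta) minimized over the two protomer orderings.

    For binary maps this is the cell mismatch count (a Hamming distance after
    ordering minimization).
    """
    d1 = float(((A - B.astype(float)) ** 2).sum())
    d2 = float(((A.T - B.astype(float)) ** 2).sum()) if A.shape == A.T.shape else np.inf
    return min(d1, d2)


@dataclass
class InterfaceClusters:
    labels: np.ndarray
    k: int
    silhouette: float
    names: list[str]           # majority interface name per cluster
    merged_labels: np.ndarray  # after merging clusters with identical names


def cluster_interfaces(cmaps: list[ContactMap], topology,
                       k_range=range(2, 13), seed: int = 0) -> InterfaceClusters:
    """k-means over canonicalized, vectorized contact maps.

    k is chosen by silhouette (computed with the ordering-minimized
    dissimilarity) over ``k_range``; clusters sharing an identical majority
    interface name are merged for reporting.
    """
    if len(cmaps) < 2:
        raise ValueError("need at least two contact maps")
    canon = [canonicalize(c, topology) for c in cmaps]
    X = np.stack([c.D.astype(np.float32).ravel() for c in canon])
    n = len(X)
    # ordering-minimized pairwise distances for the silhouette; for binary
    # maps ||A - B||^2 = |A| + |B| - 2 A.B, so both orderings come from two
    # Gram matrices
    Xt = np.stack([c.D.T.astype(np.float32).ravel() for c in canon])
    sq = (X ** 2).sum(axis=1)
    d2_direct = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    d2_swapped = sq[:, None] + sq[None, :] - 2 * (Xt @ X.T)
    dist = np.sqrt(np.maximum(np.minimum(d2_direct, d2_swapped), 0.0))
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    best = None
    for k in k_range:
        if k >= n:
            if best is None:
                raise ValueError(f"k={k} exceeds the number of maps ({n})")
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = silhouette_score(dist, km.labels_, metric="precomputed")
        if best is None or s > best[0]:
            best = (s, k, km.labels_)
    if best is None:
        raise ValueError("no valid clustering in k_range")
    s, k, labels = best
    names = []
    for c in range(k):
        members = [name_interface(canon[i], topology, canonical=False)[0]
                   for i in np.nonzero(labels == c)[0]]
        names.append(pd.Series(members).mode().iloc[0])
    # merge clusters that resolved to the same interface name
    merged = labels.copy()
    seen: dict[str, int] = {}
    for c, nm in enumerate(names):
        tgt = seen.setdefault(nm, c)
        if tgt != c:
            merged[labels == c] = tgt
    return InterfaceClusters(labels, k, float(s), names, merged)


# ---------------------------------------------------------------------------
# monomers, oligomers, RMSD
# ---------------------------------------------------------------------------

def count_monomers(trajs, topology, min_distance: float = MONOMER_MIN_DISTANCE):
    """Per-frame number of isolated receptors (COM >= 5 nm from all others).

    Returns (per_replica (R, n_frames), replica mean (n_frames,)).
    """
    if not isinstance(trajs, (list, tuple)):
        trajs = [trajs]
    series = []
    for t in trajs:
        coms = protein_coms(t, topology)
        series.append(monomer_mask(coms, t.box, min_distance).sum(axis=1))
    arr = np.stack(series)
    return arr, arr.mean(axis=0)


@dataclass
class Oligomer:
    members: list[int]                      # protein ids
    edges: list[tuple[int, int, str]]       # (i, j, interface name)
    labels: dict[int, str]                  # protein id -> subscript A, B, C...

    def edge_names(self) -> list[str]:
        out = []
        for i, j, nm in self.edges:
            s1, s2 = nm.split("/")
            out.append(f"{s1}_{self.labels[i]}/{s2}_{self.labels[j]}")
        return out


def detect_oligomers(dimers: list[tuple[int, int, str]], n_proteins: int,
                     min_size: int = 3) -> list[Oligomer]:
    """Connected components of the dimer graph with size >= min_size."""
    adj = np.zeros((n_proteins, n_proteins), dtype=bool)
    for i, j, _ in dimers:
        adj[i, j] = adj[j, i] = True
    _, comp = connected_components(adj, directed=False)
    out = []
    for c in np.unique(comp):
        members = sorted(np.nonzero(comp == c)[0].tolist())
        if len(members) < min_size or not any(adj[m].any() for m in members):
            continue
        labels = {m: chr(ord("A") + k) for k, m in enumerate(members)}
        edges = [(i, j, nm) for i, j, nm in dimers if i in members]
        out.append(Oligomer(members, edges, labels))
    return out


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD (nm) after optimal least-squares superposition of P onto Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or len(P) < 3:
        raise ValueError("need matched coordinate sets of >= 3 beads")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


def interface_rmsd(dimer_coords: np.ndarray, reference_coords: np.ndarray) -> float:
    """Interface RMSD in Angstrom.

    The caller supplies matched backbone-bead coordinates of the interface
    helices of both protomers of each dimer (CG backbone beads standing in
    for C-alpha); superposition is over the full dimer selection.
    """
    return kabsch_rmsd(dimer_coords, reference_coords) * 10.0
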