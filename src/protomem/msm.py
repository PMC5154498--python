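"""Markov-state kinetic model of cholesterol movement and its flux pathways.

Microstates are geometric clusters of the ROH-backbone contact fingerprints
(plus z-zone); the transition matrix is the detailed-balance-symmetrized
maximum-likelihood estimate at a sliding-window lag; macrostates come from
spectral (PCCA-like) lumping of the leading eigenvectors into 8 kinetic sets.
Source-to-sink kinetics are characterized with transition-path theory:
committors, net reactive flux, and the top-k pathways by iterative bottleneck
decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_N_MICRO = 100
DEFAULT_LAG = 5
DEFAULT_N_MACRO = 8
MIN_TRANSITIONS_PER_MICRO = 10


# ---------------------------------------------------------------------------
# estimation primitives
# ---------------------------------------------------------------------------

def count_matrix(dtrajs: list[np.ndarray], n_states: int, lag: int) -> np.ndarray:
    """Sliding-window transition counts at the given lag."""
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        d = np.asarray(d, dtype=int)
        if len(d) > lag:
            np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def largest_connected_set(C: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph."""
    from scipy.sparse.csgraph import connected_components
    n, labels = connected_components(C > 0, directed=True, connection="strong")
    sizes = np.bincount(labels)
    return np.nonzero(labels == np.argmax(sizes))[0]


def transition_matrix(C: np.ndarray, reversible: bool = True) -> np.ndarray:
    """Row-stochastic transition matrix; reversible via count symmetrization.

    The symmetrized estimate T_ij = (C_ij + C_ji) / sum_j (C_ij + C_ji)
    satisfies detailed balance exactly with pi proportional to the symmetrized
    row sums.
    """
    C = np.asarray(C, dtype=float)
    if reversible:
        C = 0.5 * (C + C.T)
    rows = C.sum(axis=1, keepdims=True)
    if np.any(rows == 0):
        raise ValueError("count matrix has an unvisited state; restrict first")
    return C / rows


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of T, normalized to a probability vector."""
    vals, vecs = np.linalg.eig(T.T)
    k = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def implied_timescales(T: np.ndarray, lag_time: float, n: int = 5) -> np.ndarray:
    """t_i = -lag / ln |lambda_i| for the leading non-unit eigenvalues."""
    vals = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
    vals = vals[1:n + 1]
    with np.errstate(divide="ignore"):
        return -lag_time / np.log(np.clip(vals, 1e-15, 1 - 1e-15))


# ---------------------------------------------------------------------------
# committors and flux
# ---------------------------------------------------------------------------

def forward_committor(T: np.ndarray, source, sink) -> np.ndarray:
    """q+_i: probability of reaching the sink before the source from i."""
    n = T.shape[0]
    source = np.atleast_1d(source)
    sink = np.atleast_1d(sink)
    q = np.zeros(n)
    q[sink] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([source, sink]))
    if len(inter):
        A = np.eye(len(inter)) - T[np.ix_(inter, inter)]
        b = T[np.ix_(inter, sink)].sum(axis=1)
        q[inter] = np.linalg.solve(A, b)
    return q


def backward_committor(T: np.ndarray, pi: np.ndarray, source, sink) -> np.ndarray:
    """q-_i via the time-reversed chain (equals 1 - q+ for reversible T)."""
    Trev = (pi[None, :] * T.T) / pi[:, None]
    return forward_committor(Trev, sink, source)


def net_flux_matrix(T: np.ndarray, pi: np.ndarray, source, sink) -> np.ndarray:
    """Net reactive flux f+_ij = max(0, f_ij - f_ji), f_ij = pi_i q-_i T_ij q+_j."""
    qp = forward_committor(T, source, sink)
    qm = backward_committor(T, pi, source, sink)
    F = pi[:, None] * qm[:, None] * T * qp[None, :]
    np.fill_diagonal(F, 0.0)
    return np.maximum(F - F.T, 0.0)


def total_flux(F: np.ndarray, source) -> float:
    source = np.atleast_1d(source)
    return float(F[source, :].sum() - F[np.ix_(source, source)].sum())


def _widest_path(F: np.ndarray, source: int, sink: int):
    """Path maximizing the minimum edge flux (Dijkstra on max-min capacity)."""
    n = F.shape[0]
    best = np.full(n, -np.inf)
    best[source] = np.inf
    prev = np.full(n, -1)
    visited = np.zeros(n, dtype=bool)
    while True:
        cand = np.where(visited, -np.inf, best)
        u = int(np.argmax(cand))
        if cand[u] == -np.inf:
            return None, 0.0
        if u == sink:
            break
        visited[u] = True
        width = np.minimum(best[u], F[u])
        upd = width > best
        best[upd] = width[upd]
        prev[upd] = u
    path = [sink]
    while path[-1] != source:
        path.append(int(prev[path[-1]]))
    path.reverse()
    bottleneck = min(F[a, b] for a, b in zip(path, path[1:]))
    return path, float(bottleneck)


@dataclass
class Pathway:
    states: list[int]
    flux: float
    fraction: float


def flux_pathways(T: np.ndarray, pi: np.ndarray, source: int, sink: int,
                  k: int = 5) -> list[Pathway]:
    """Top-k source->sink pathways by iterative bottleneck decomposition.

    Each round removes the widest (max-min flux) path's bottleneck flux from
    its edges; pathway fluxes are non-increasing and their fractions are
    relative to the total reactive flux.
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    F = net_flux_matrix(T, pi, source, sink)
    total = total_flux(F, source)
    if total <= 0:
        logger.warning("zero total reactive flux; no pathways")
        return []
    out: list[Pathway] = []
    W = F.copy()
    for _ in range(k):
        path, f = _widest_path(W, source, sink)
        if path is None or f <= 1e-15:
            break
        for a, b in zip(path, path[1:]):
            W[a, b] -= f
        out.append(Pathway(path, f, f / total))
    return out


# ---------------------------------------------------------------------------
# the cholesterol model
# ---------------------------------------------------------------------------

@dataclass
class CholKineticModel:
    microstate_centers: np.ndarray       # (n_micro, n_features)
    dtrajs: list[np.ndarray]             # microstate assignment per CHOL
    count_mat: np.ndarray
    T: np.ndarray                        # row-stochastic, reversible
    pi: np.ndarray
    macro_of_micro: np.ndarray           # (n_micro,) macrostate labels
    lag: int
    lag_time_ns: float
    active_set: np.ndarray               # original microstates kept

    @property
    def n_micro(self) -> int:
        return self.T.shape[0]

    @property
    def n_macro(self) -> int:
        return int(self.macro_of_micro.max()) + 1

    def macro_stationary(self) -> np.ndarray:
        out = np.zeros(self.n_macro)
        np.add.at(out, self.macro_of_micro, self.pi)
        return out

    def macro_transition_matrix(self) -> np.ndarray:
        """Stationary-weighted coarse-graining of T onto the macrostates."""
        n = self.n_macro
        M = np.zeros((n, n))
        flux = self.pi[:, None] * self.T
        for a in range(n):
            ia = self.macro_of_micro == a
            for b in range(n):
                ib = self.macro_of_micro == b
                M[a, b] = flux[np.ix_(ia, ib)].sum()
        rows = M.sum(axis=1, keepdims=True)
        return M / np.where(rows > 0, rows, 1.0)

    def implied_timescales(self, n: int = 5) -> np.ndarray:
        return implied_timescales(self.T, self.lag_time_ns, n)

    def macrostate_fingerprint(self, features_of_micro: np.ndarray | None = None
                               ) -> np.ndarray:
        """pi-weighted mean fingerprint per macrostate."""
        feats = (self.microstate_centers if features_of_micro is None
                 else features_of_micro)
        out = np.zeros((self.n_macro, feats.shape[1]))
        w = np.zeros(self.n_macro)
        for a in range(self.n_macro):
            ia = self.macro_of_micro == a
            out[a] = (self.pi[ia, None] * feats[ia]).sum(axis=0)
            w[a] = self.pi[ia].sum()
        return out / np.where(w[:, None] > 0, w[:, None], 1.0)

    def bulk_macrostates(self) -> tuple[int, int]:
        """(upper-bulk, lower-bulk): no protein contacts, head zones.

        The fingerprint layout is [residue contacts..., upper, middle, lower].
        """
        fp = self.macrostate_fingerprint()
        contacts = fp[:, :-3].sum(axis=1)
        upper_score = fp[:, -3] - contacts
        lower_score = fp[:, -1] - contacts
        return int(np.argmax(upper_score)), int(np.argmax(lower_score))


def _spectral_lump(T: np.ndarray, pi: np.ndarray, n_macro: int,
                   seed: int = 0) -> np.ndarray:
    """PCCA-like lumping: k-means on the leading eigenvector components.

    Eigenvector columns are normalized in the pi-weighted norm and microstates
    are weighted by pi in the k-means objective, so kinetically dominant
    states (the leaflet bulks) drive the partition rather than rare contact
    states whose pi^{-1/2}-scaled components would otherwise dominate.
    """
    n = T.shape[0]
    n_macro = min(n_macro, n)
    if n_macro >= n:
        return np.arange(n)
    # symmetrize in the pi inner product for stable real eigenvectors
    s = np.sqrt(pi)
    S = (s[:, None] * T) / s[None, :]
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    psi = vecs[:, order[:n_macro]] / s[:, None]
    norms = np.sqrt(np.sum(pi[:, None] * psi ** 2, axis=0))
    psi = psi / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=n_macro, n_init=10, random_state=seed)
    return km.fit_predict(psi, sample_weight=pi)


def build_chol_msm(fingerprints: np.ndarray, n_micro: int = DEFAULT_N_MICRO,
                   lag: int = DEFAULT_LAG, n_macro: int = DEFAULT_N_MACRO,
                   stride_ns: float = 1.0, seed: int = 0) -> CholKineticModel:
    """Kinetic model from per-CHOL fingerprint series.

    ``fingerprints`` is (n_molecules, n_frames, n_features).  Distinct
    fingerprints are used directly as microstates when they number at most
    ``n_micro``; otherwise k-means clusters them geometrically.  Microstates
    visited fewer than 10 times in transitions are merged into their nearest
    retained centroid.  The chain is restricted to its largest connected set
    (with a warning when that drops states).
    """
    fp = np.asarray(fingerprints)
    n_mol, n_frames, n_feat = fp.shape
    flat = fp.reshape(-1, n_feat)
    uniq, inverse, mult = np.unique(flat, axis=0, return_inverse=True,
                                    return_counts=True)
    if len(uniq) <= n_micro:
        centers = uniq.astype(float)
        labels = inverse
    else:
        # cluster the distinct fingerprints, weighted by their multiplicity:
        # equivalent to k-means over all samples but orders of magnitude cheaper
        km = KMeans(n_clusters=n_micro, n_init=4, random_state=seed)
        uniq_labels = km.fit_predict(uniq.astype(float), sample_weight=mult)
        labels = uniq_labels[inverse]
        centers = km.cluster_centers_
    dtrajs = [labels.reshape(n_mol, n_frames)[m] for m in range(n_mol)]

    C = count_matrix(dtrajs, len(centers), lag)
    # merge rare microstates into the nearest retained centroid
    occupancy = C.sum(axis=1) + C.sum(axis=0)
    rare = occupancy < MIN_TRANSITIONS_PER_MICRO
    if np.any(rare) and not np.all(rare):
        keep = np.nonzero(~rare)[0]
        remap = np.arange(len(centers))
        for s in np.nonzero(rare)[0]:
            d = np.linalg.norm(centers[keep] - centers[s], axis=1)
            remap[s] = keep[np.argmin(d)]
        # compress labels
        new_ids = {s: i for i, s in enumerate(keep)}
        remap = np.array([new_ids[remap[s]] for s in range(len(centers))])
        dtrajs = [remap[d] for d in dtrajs]
        centers = centers[keep]
        C = count_matrix(dtrajs, len(centers), lag)

    lcs = largest_connected_set(C)
    if len(lcs) < len(centers):
        logger.warning("restricting to largest connected set: %d of %d microstates",
                       len(lcs), len(centers))
        pos = -np.ones(len(centers), dtype=int)
        pos[lcs] = np.arange(len(lcs))
        dtrajs = [pos[d][pos[d] >= 0] for d in dtrajs]
        centers = centers[lcs]
        C = count_matrix(dtrajs, len(centers), lag)
    T = transition_matrix(C, reversible=True)
    pi = stationary_distribution(T)
    macro = _spectral_lump(T, pi, n_macro, seed=seed)
    return CholKineticModel(
        microstate_centers=centers, dtrajs=dtrajs, count_mat=C, T=T, pi=pi,
        macro_of_micro=macro, lag=lag, lag_time_ns=lag * stride_ns,
        active_set=lcs,
    )
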