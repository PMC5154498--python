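"""Membrane modulation between protomer pairs: order/thickness as f(r, d).

For a pair of protomers at COM separation r, lipid positions are decomposed in
the frame of the line of centers: d along the axis (measured from protomer 1,
growing toward protomer 2) and n perpendicular to it.  Samples are kept when
|n| < r0 (r0 = 1.7 nm, the average protomer radius) and d in [r0, r - r0], for
pairs whose relative orientations alpha, beta fall in the interface windows
[alpha0 +/- pi/6], [beta0 +/- pi/6], and only for frames where no third
protein lies within r0 of the COM-COM segment (line-of-centers occlusion).

alpha (resp. beta) is the signed angle from the axis toward the partner to the
protomer's internal reference direction (COM -> TM1 projection): alpha0 = 0
selects the TM1,2,H8 face, alpha0 = -3*pi/4 the TM5,6 face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ScalarField2D, thickness_map
from .geometry import min_image_displacement, point_segment_distance_xy, unwrap_about
from .order import lipid_order_samples
from .receptor import protein_coms, reference_angle, wrap_angle

R0_PROTOMER = 1.7            #: average protomer radius (nm)
ANGULAR_HALF_WIDTH = np.pi / 6
ALPHA0_TM128 = 0.0           #: interface window preset for the TM1,2,H8 face
ALPHA0_TM56 = -3 * np.pi / 4  #: interface window preset for the TM5,6 face


@dataclass(frozen=True)
class InterfaceWindow:
    """Angular windows selecting which faces of the two protomers meet."""

    alpha0: float
    beta0: float
    half_width: float = ANGULAR_HALF_WIDTH

    def contains(self, alpha, beta) -> np.ndarray:
        da = np.abs(wrap_angle(np.asarray(alpha) - self.alpha0))
        db = np.abs(wrap_angle(np.asarray(beta) - self.beta0))
        return (da <= self.half_width) & (db <= self.half_width)


def protomer_orientation(positions, protein, v_d, box=None) -> float:
    """Signed angle from the in-plane axis ``v_d`` to the protomer's internal
    reference direction (COM -> TM1 projection), in (-pi, pi]."""
    v = np.asarray(v_d, dtype=float)[:2]
    axis_angle = np.arctan2(v[1], v[0])
    return float(wrap_angle(reference_angle(positions, protein, box=box) - axis_angle))


@dataclass
class PairProfile:
    window: InterfaceWindow
    r_edges: np.ndarray
    d_edges: np.ndarray
    r0: float = R0_PROTOMER
    order_sum: np.ndarray = None
    order_count: np.ndarray = None
    thickness_sum: np.ndarray = None
    thickness_count: np.ndarray = None

    def __post_init__(self):
        shape = (len(self.r_edges) - 1, len(self.d_edges) - 1)
        for name in ("order_sum", "order_count", "thickness_sum", "thickness_count"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(shape))

    def order_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.order_count > 0,
                            self.order_sum / self.order_count, np.nan)

    def thickness_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.thickness_count > 0,
                            self.thickness_sum / self.thickness_count, np.nan)


def default_r_edges() -> np.ndarray:
    return np.arange(3.0, 12.0 + 1e-9, 0.25)


def default_d_edges() -> np.ndarray:
    return np.arange(0.0, 12.0 + 1e-9, 0.25)


def select_pair_frames(traj, topology, window: InterfaceWindow,
                       r_max: float = np.inf, r0: float = R0_PROTOMER,
                       coms: np.ndarray | None = None) -> list[tuple[int, int, int]]:
    """Ordered (frame, protomer_1, protomer_2) triples passing the window and
    the occlusion filter (no third COM within r0 of the COM-COM segment)."""
    if coms is None:
        coms = protein_coms(traj, topology)
    out = []
    n_p = coms.shape[1]
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        angles = [reference_angle(pos, p, box=traj.box) for p in topology.proteins]
        for i in range(n_p):
            for j in range(n_p):
                if i == j:
                    continue
                dvec = min_image_displacement(coms[f, i], coms[f, j], traj.box)
                r = np.linalg.norm(dvec[:2])
                if r == 0 or r > r_max:
                    continue
                axis_angle = np.arctan2(dvec[1], dvec[0])
                alpha = wrap_angle(angles[i] - axis_angle)
                beta = wrap_angle(angles[j] - (axis_angle + np.pi))
                if not window.contains(alpha, beta):
                    continue
                # occlusion: third-protein COMs, unwrapped about protomer i
                others = [k for k in range(n_p) if k not in (i, j)]
                if others:
                    oc = unwrap_about(coms[f, others], coms[f, i], traj.box)
                    a = coms[f, i]
                    b = a + dvec
                    if np.min(point_segment_distance_xy(oc, a, b)) < r0:
                        continue
                out.append((f, i, j))
    return out


def accumulate_pair_profile(traj, topology, window: InterfaceWindow,
                            r_edges=None, d_edges=None, r0: float = R0_PROTOMER,
                            thickness_field: ScalarField2D | None = None,
                            pairs=None) -> PairProfile:
    """Average order and local thickness over (r, d) bins for an interface.

    The local thickness entering the profile is the gridded thickness field
    sampled at the lipid position (computed over the whole trajectory unless
    one is supplied).  Returns an all-missing profile with a warning when no
    pair qualifies.
    """
    import logging
    r_edges = default_r_edges() if r_edges is None else np.asarray(r_edges)
    d_edges = default_d_edges() if d_edges is None else np.asarray(d_edges)
    prof = PairProfile(window, r_edges, d_edges, r0=r0)
    if thickness_field is None:
        thickness_field = thickness_map(traj, topology)
    thick_mean = thickness_field.mean()
    thick_occ = thickness_field.occupied()
    coms = protein_coms(traj, topology)
    if pairs is None:
        pairs = select_pair_frames(traj, topology, window,
                                   r_max=r_edges[-1], r0=r0, coms=coms)
    if not pairs:
        logging.getLogger(__name__).warning("no qualifying pair frames; profile empty")
        return prof
    samples_cache: dict[int, object] = {}
    for f, i, j in pairs:
        pos = traj.positions[f]
        if f not in samples_cache:
            samples_cache[f] = lipid_order_samples(pos, topology, frame_index=f)
        s = samples_cache[f]
        dvec = min_image_displacement(coms[f, i], coms[f, j], traj.box)[:2]
        r = float(np.linalg.norm(dvec))
        if not (r_edges[0] <= r < r_edges[-1]):
            continue
        v_d = dvec / r
        n_d = np.array([-v_d[1], v_d[0]])
        disp = min_image_displacement(
            coms[f, i], np.c_[s.xy, np.full(len(s), coms[f, i][2])], traj.box)[:, :2]
        d = disp @ v_d
        n = disp @ n_d
        keep = (np.abs(n) < r0) & (d >= r0) & (d <= r - r0)
        if not np.any(keep):
            continue
        ri = int(np.searchsorted(r_edges, r, side="right") - 1)
        di = np.clip(np.searchsorted(d_edges, d[keep], side="right") - 1,
                     0, len(d_edges) - 2)
        np.add.at(prof.order_sum[ri], di, s.chi[keep])
        np.add.at(prof.order_count[ri], di, 1.0)
        bx, by = thickness_field.bin_indices(s.xy[keep])
        has_t = thick_occ[bx, by]
        np.add.at(prof.thickness_sum[ri], di[has_t], thick_mean[bx[has_t], by[has_t]])
        np.add.at(prof.thickness_count[ri], di[has_t], 1.0)
    return prof
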