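"""Synthetic coarse-grained membrane-protein trajectories with ground truth.

This generator is a statistical emulator of multi-microsecond coarse-grained
simulations of receptor arrays in a mixed plasma membrane.  It produces bead
trajectories whose statistics are planted and therefore exactly known:

* a two-leaflet bilayer with configurable per-leaflet headgroup composition
  (defaults mirror an idealized mammalian plasma membrane: ~30% CHOL, ~5% GM
  in the upper leaflet, ~19% charged lipids in the lower leaflet, with minor
  CER/LPC/DAG/PA/PIP fractions);
* laterally diffusing lipids carrying a latent order angle that relaxes
  toward a spatially structured mean field (elevated order near configured
  helices, depressed near others), realized in the tail-bead geometry;
* sphingomyelin whose spatial density is tilted toward ordered regions with a
  configurable coupling strength;
* flip-capable sterols/lipids (CHOL, CER, DAG) switching leaflets as a
  Poisson telegraph process at a planted rate, with a continuous z path
  through the midplane;
* 16 rigid protomers (inactive/active) on a regular grid with random initial
  z-rotations that diffuse, rotate, and bind at planted dimer interfaces.

Every stochastic element derives from a single seed; identical parameters and
seed give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import min_image_displacement, wrap_positions
from .topology import (DEFAULT_HELIX_MAP, FIRST_RESIDUE, LAST_RESIDUE,
                       LipidSpecies, ProteinTopology, SystemTopology,
                       default_species)
from .trajectory import Trajectory, TrajectoryFrame

# -- default leaflet compositions (mole fractions per headgroup class) -------
DEFAULT_UPPER_COMPOSITION: dict[str, float] = {
    "PC": 0.329, "PE": 0.15, "SM": 0.15, "CHOL": 0.30, "GM": 0.05,
    "CER": 0.007, "LPC": 0.010, "DAG": 0.004,
}
DEFAULT_LOWER_COMPOSITION: dict[str, float] = {
    "PC": 0.254, "PE": 0.20, "SM": 0.05, "CHOL": 0.30,
    "PS": 0.079, "PI": 0.080, "PA": 0.015, "PIP1": 0.016,
    "CER": 0.001, "DAG": 0.005,
}

#: lipids per nm^2 per leaflet; 50x50 nm with 16 receptors gives 3200 upper /
#: 3000 lower lipids (protein:lipid ~ 1:200), 25x25 nm gives 800 / 750 (1:100).
LIPID_DENSITY_UPPER = 3200 / 2500.0
LIPID_DENSITY_LOWER = 3000 / 2500.0

LINKER_Z = 2.0        #: |z| of non-flipping first linker beads (nm)
FLIP_REF_Z = 1.7      #: |z| of CHOL ROH / CER/DAG linker at rest (nm)
HEAD_DZ = 0.3         #: headgroup bead offset above the linker (nm)
TAIL_BOND = 0.4       #: tail bead spacing (nm)
GL2_OFFSET = 0.25     #: lateral offset of the second linker bead (nm)
FOOTPRINT_RADIUS = 2.0  #: protein footprint excluded to lipids (nm)

# protein template: helix -> (azimuth deg, radius nm); TM5,6 sit near +135 deg
# so the TM5,6 interface window (alpha0 = -3*pi/4) faces them, TM1 defines 0.
_HELIX_AZIMUTH = {"TM1": 0.0, "TM2": -50.0, "TM3": -110.0, "TM4": -160.0,
                  "TM5": 155.0, "TM6": 115.0, "TM7": 60.0, "H8": 25.0}
_HELIX_RADIUS = {"TM1": 1.3, "TM2": 1.3, "TM3": 0.8, "TM4": 1.3,
                 "TM5": 1.3, "TM6": 1.3, "TM7": 1.3, "H8": 1.0}
_HELIX_Z = 2.1        #: TM helices span -_HELIX_Z .. +_HELIX_Z
_SC_DR = 0.3          #: sidechain bead radial offset


@dataclass(frozen=True)
class PlantedInterface:
    """A dimerization interface the generator can bind protomers into."""

    name: str
    alpha0: float
    beta0: float
    bound_distance: float = 3.2   # COM-COM separation when bound (nm)
    capture_radius: float = 4.5   # nm
    capture_half_width: float = np.pi / 6
    k_on_per_ns: float = 0.1
    k_off_per_ns: float = 0.0     # 0: interfaces never dissociate


def default_interface_library() -> list[PlantedInterface]:
    return [
        PlantedInterface("TM1,2,H8/TM1,2,H8", 0.0, 0.0),
        PlantedInterface("TM1,2,H8/TM5,6", 0.0, -3 * np.pi / 4),
        PlantedInterface("TM5,6/TM5,6", -3 * np.pi / 4, -3 * np.pi / 4),
    ]


@dataclass
class GeneratorParams:
    patch_nm: float = 50.0
    box_height_nm: float = 11.0
    n_proteins: int = 16
    conformations: str = "inactive"      # "inactive" | "active" | "mixed"
    initial_orientations: list | None = None  # z-rotations (rad); None = random
    upper_composition: dict = field(default_factory=lambda: dict(DEFAULT_UPPER_COMPOSITION))
    lower_composition: dict = field(default_factory=lambda: dict(DEFAULT_LOWER_COMPOSITION))
    lipid_density_upper: float = LIPID_DENSITY_UPPER
    lipid_density_lower: float = LIPID_DENSITY_LOWER
    d_lipid_nm2_ns: float = 0.01
    d_protein_nm2_ns: float = 0.002
    d_rot_rad2_ns: float = 0.001
    psi_d_rad2_ns: float = 0.05          # tail-azimuth wander
    baseline_chi: float = 0.6            # mean order angle far from proteins (rad)
    helix_order_bias: dict = field(default_factory=lambda: {
        "TM1": -0.10, "TM4": +0.12, "TM5": -0.12, "TM6": -0.12})
    order_corr_length_nm: float = 1.5
    background_order_sd: float = 0.05    # membrane-wide order/disorder domains (rad)
    background_corr_nm: float = 3.0
    chi_relax_ns: float = 5.0
    chi_sd: float = 0.12                 # stationary sd of the order angle
    sm_coupling: float = 0.6             # SM density tilt toward ordered regions
    thickness_order_coupling: float = 0.3  # nm of linker-z per rad of field
    flip_rates_per_s: dict = field(default_factory=lambda: {
        "CHOL": 7.23e6, "DAG": 6.34e6, "CER": 0.0})
    flip_transit_frames: int = 2
    interface_library: list = field(default_factory=default_interface_library)
    planted_bonds: list = field(default_factory=list)  # (i, j, interface_index)
    stride_ns: float = 1.0
    n_frames: int = 100
    seed: int = 0
    store_chi: bool = True

    def validate(self) -> None:
        for name, comp in (("upper", self.upper_composition),
                           ("lower", self.lower_composition)):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} leaflet mole fractions must sum to 1")
        rates = list(self.flip_rates_per_s.values())
        if any(r < 0 for r in rates):
            raise ValueError("flip rates must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters plus the realized event record of one run."""

    params: GeneratorParams
    flip_events: pd.DataFrame    # molecule, species, frame, time_ns, direction
    dimer_episodes: pd.DataFrame  # protein_i, protein_j, interface, frame_start, frame_end
    chi_series: np.ndarray | None  # (n_frames, n_lipids) float32
    helix_field_centers: np.ndarray | None = None


def replay_ground_truth(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Event tables keyed by frame index, for test assertions."""
    flips = truth.flip_events.sort_values(["frame", "molecule"]).reset_index(drop=True)
    dimers = truth.dimer_episodes.sort_values(["frame_start"]).reset_index(drop=True)
    return {"flips": flips, "dimer_episodes": dimers}


# ---------------------------------------------------------------------------
# protein template
# ---------------------------------------------------------------------------

def _protein_template(conformation: str):
    """Idealized 8-helix bundle: BB bead per residue + one SC bead each.

    Returns (bb (n_res, 3), sc (n_res, 3), residue_numbers, helix_map) in the
    internal frame (TM1 toward +x).  The active conformation swings TM6
    outward (larger radius, shifted azimuth), mimicking activation.
    """
    azimuth = dict(_HELIX_AZIMUTH)
    radius = dict(_HELIX_RADIUS)
    if conformation == "active":
        azimuth["TM6"] = 100.0
        radius["TM6"] = 1.6
    res = np.arange(FIRST_RESIDUE, LAST_RESIDUE + 1)
    n = len(res)
    bb = np.zeros((n, 3))
    sc_dir = np.zeros((n, 2))
    helix_of = np.full(n, "", dtype=object)
    for hx, (lo, hi) in DEFAULT_HELIX_MAP.items():
        mask = (res >= lo) & (res <= hi)
        helix_of[mask] = hx
    down = {"TM1": True, "TM2": False, "TM3": True, "TM4": False,
            "TM5": True, "TM6": False, "TM7": True}
    for i, r in enumerate(res):
        hx = helix_of[i]
        if hx and hx != "H8":
            lo, hi = DEFAULT_HELIX_MAP[hx]
            frac = (r - lo) / (hi - lo)
            z = _HELIX_Z * (1 - 2 * frac) if down[hx] else _HELIX_Z * (2 * frac - 1)
            a = np.deg2rad(azimuth[hx])
            rad = radius[hx]
            # slight super-helical wobble so the covariance is non-degenerate
            a = a + 0.06 * np.sin(2 * np.pi * frac)
            bb[i] = (rad * np.cos(a), rad * np.sin(a), z)
            sc_dir[i] = (np.cos(a), np.sin(a))
        elif hx == "H8":
            lo, hi = DEFAULT_HELIX_MAP["H8"]
            frac = (r - lo) / (hi - lo)
            a = np.deg2rad(azimuth["H8"])
            rad = radius["H8"] + 1.2 * frac
            bb[i] = (rad * np.cos(a), rad * np.sin(a), -2.0)
            sc_dir[i] = (np.cos(a), np.sin(a))
    # loops and termini: interpolate azimuth between flanking helices
    helix_list = list(DEFAULT_HELIX_MAP.items())
    for i, r in enumerate(res):
        if helix_of[i]:
            continue
        prev_h = next_h = None
        for hx, (lo, hi) in helix_list:
            if hi < r:
                prev_h = hx
            if lo > r and next_h is None:
                next_h = hx
        if prev_h is None:       # N-terminal tail before TM1
            a0 = a1 = azimuth["TM1"]
            z = _HELIX_Z + 0.2
        elif next_h is None:     # C-terminal tail after H8: compact coil
            k = r - DEFAULT_HELIX_MAP["H8"][1]
            a = np.deg2rad(azimuth["H8"]) + 0.25 * k
            bb[i] = (2.0 * np.cos(a), 2.0 * np.sin(a), -2.35)
            sc_dir[i] = (np.cos(a), np.sin(a))
            continue
        else:
            lo_p, hi_p = DEFAULT_HELIX_MAP[prev_h]
            lo_n, hi_n = DEFAULT_HELIX_MAP[next_h]
            t = (r - hi_p) / max(lo_n - hi_p, 1)
            a0, a1 = azimuth[prev_h], azimuth[next_h]
            # extracellular loop if the previous helix runs upward at its end
            up_end = not down.get(prev_h, False)
            z = (_HELIX_Z + 0.2) * (1 if up_end else -1)
        a = np.deg2rad(a0 + (a1 - a0) * (t if prev_h and next_h else 0.0))
        bb[i] = (1.5 * np.cos(a), 1.5 * np.sin(a), z)
        sc_dir[i] = (np.cos(a), np.sin(a))
    # normalize the internal frame: backbone COM at the origin and the
    # COM -> TM1-COM direction along +x, so the lab rotation angle IS the
    # reference direction used by all receptor-frame analyses
    bb[:, :2] -= bb[:, :2].mean(axis=0)
    tm1 = bb[(res >= DEFAULT_HELIX_MAP["TM1"][0]) &
             (res <= DEFAULT_HELIX_MAP["TM1"][1])][:, :2].mean(axis=0)
    ang = np.arctan2(tm1[1], tm1[0])
    c, s = np.cos(-ang), np.sin(-ang)
    R2 = np.array([[c, -s], [s, c]])
    bb[:, :2] = bb[:, :2] @ R2.T
    sc_dir = sc_dir @ R2.T
    sc = bb.copy()
    sc[:, :2] += _SC_DR * sc_dir
    return bb, sc, res, dict(DEFAULT_HELIX_MAP)


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    names = list(fractions)
    exact = np.array([fractions[k] * n for k in names])
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(exact - counts))
    for idx in order[:short]:
        counts[idx] += 1
    return dict(zip(names, counts.tolist()))


class _Builder:
    """Shared state between build_system and simulate (bead construction)."""

    def __init__(self, params: GeneratorParams):
        params.validate()
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.box = np.array([params.patch_nm, params.patch_nm, params.box_height_nm])
        self._make_background()

    def _make_background(self) -> None:
        """Static membrane-wide order/disorder domains: a periodic Gaussian
        random field (FFT-smoothed white noise) added to the mean order."""
        if self.p.background_order_sd <= 0:
            self.bg = None
            return
        n = max(8, int(round(self.p.patch_nm)))
        noise = self.rng.standard_normal((n, n))
        k = np.fft.fftfreq(n, d=self.p.patch_nm / n)
        kx, ky = np.meshgrid(k, k, indexing="ij")
        filt = np.exp(-2 * np.pi ** 2 * self.p.background_corr_nm ** 2
                      * (kx ** 2 + ky ** 2))
        f = np.real(np.fft.ifft2(np.fft.fft2(noise) * filt))
        f -= f.mean()
        f /= f.std()
        self.bg = f * self.p.background_order_sd

    def _background_at(self, xy: np.ndarray) -> np.ndarray:
        n = self.bg.shape[0]
        h = self.p.patch_nm / n
        gx, gy = xy[:, 0] / h, xy[:, 1] / h
        i0 = np.floor(gx).astype(int) % n
        j0 = np.floor(gy).astype(int) % n
        fx, fy = gx - np.floor(gx), gy - np.floor(gy)
        i1, j1 = (i0 + 1) % n, (j0 + 1) % n
        return (self.bg[i0, j0] * (1 - fx) * (1 - fy)
                + self.bg[i1, j0] * fx * (1 - fy)
                + self.bg[i0, j1] * (1 - fx) * fy
                + self.bg[i1, j1] * fx * fy)

    # -- order mean field -------------------------------------------------
    def field_centers(self, prot_xy: np.ndarray, prot_theta: np.ndarray):
        """(n_centers, 2) helix xy positions and (n_centers,) bias amplitudes."""
        biases = self.p.helix_order_bias
        if not len(prot_xy) or not biases:
            return np.zeros((0, 2)), np.zeros(0)
        offs, amps = [], []
        for hx, amp in biases.items():
            a = np.deg2rad(_HELIX_AZIMUTH[hx])
            offs.append((_HELIX_RADIUS[hx] * np.cos(a), _HELIX_RADIUS[hx] * np.sin(a)))
            amps.append(amp)
        offs = np.array(offs)          # (H, 2)
        amps = np.array(amps)
        c, s = np.cos(prot_theta), np.sin(prot_theta)
        centers = np.empty((len(prot_xy), len(offs), 2))
        centers[:, :, 0] = prot_xy[:, None, 0] + offs[None, :, 0] * c[:, None] - offs[None, :, 1] * s[:, None]
        centers[:, :, 1] = prot_xy[:, None, 1] + offs[None, :, 0] * s[:, None] + offs[None, :, 1] * c[:, None]
        return centers.reshape(-1, 2), np.tile(amps, len(prot_xy))

    def order_mean_field(self, xy: np.ndarray, centers: np.ndarray,
                         amps: np.ndarray) -> np.ndarray:
        m = np.full(len(xy), self.p.baseline_chi)
        if self.bg is not None and len(xy):
            m += self._background_at(np.atleast_2d(xy))
        if len(centers) == 0:
            return m
        L = np.array([self.box[0], self.box[1]])
        d = xy[:, None, :] - centers[None, :, :]
        d -= L * np.round(d / L)
        w = np.exp(-(d ** 2).sum(axis=-1) / (2 * self.p.order_corr_length_nm ** 2))
        return m + w @ amps

    # -- bead construction -------------------------------------------------
    def lipid_beads(self, sp: LipidSpecies, xy, z_ref, chi, psi) -> np.ndarray:
        """(n_mol, n_beads, 3) positions from per-molecule state."""
        n = len(xy)
        out = np.empty((n, sp.n_beads, 3))
        sgn = np.where(z_ref >= 0, 1.0, -1.0)
        dvec = np.stack([np.sin(chi) * np.cos(psi), np.sin(chi) * np.sin(psi),
                         -sgn * np.cos(chi)], axis=1)
        perp = np.stack([-np.sin(psi), np.cos(psi), np.zeros(n)], axis=1)
        ref3 = np.concatenate([xy, z_ref[:, None]], axis=1)
        linker_pos = [ref3, ref3 + GL2_OFFSET * perp]
        # map tail beads to (tail index, 1-based position along the tail):
        # templates list each tail's beads contiguously, ending at a tail-end
        tail_pos: dict[int, tuple[int, int]] = {}
        ct, k = 0, 1
        for bidx, role in enumerate(sp.bead_roles):
            if role == "tail":
                tail_pos[bidx] = (ct, k)
                k += 1
            elif role == "tail-end":
                tail_pos[bidx] = (ct, k)
                ct, k = ct + 1, 1
        n_linkers = sp.bead_roles.count("linker")
        n_head_seen = 0
        linker_seen = 0
        for bidx, role in enumerate(sp.bead_roles):
            if role == "headgroup":
                n_head_seen += 1
                out[:, bidx] = ref3.copy()
                out[:, bidx, 2] += sgn * HEAD_DZ * n_head_seen
            elif role in ("linker", "sterol-hydroxyl"):
                out[:, bidx] = linker_pos[min(linker_seen, 1)]
                linker_seen += 1
            else:
                t, kk = tail_pos[bidx]
                base = linker_pos[min(t, 1)] if n_linkers >= 2 else ref3
                out[:, bidx] = base + kk * TAIL_BOND * dvec
        out[:, :, 0] = np.mod(out[:, :, 0], self.box[0])
        out[:, :, 1] = np.mod(out[:, :, 1], self.box[1])
        return out


def build_system(params: GeneratorParams):
    """Construct the initial system: topology plus frame 0.

    Proteins sit on a regular grid with independent random z rotations; lipid
    counts follow the per-leaflet area density (16 receptors in 50x50 nm give
    3200 upper-leaflet lipids, in 25x25 nm give 800); species counts honor the
    requested mole fractions within integer rounding (largest remainder,
    deterministic).  Lipids are placed uniformly outside protein footprints,
    sphingomyelin biased by the planted order-coupling.
    """
    b = _Builder(params)
    p = params
    rng = b.rng

    # protein grid
    n_prot = p.n_proteins
    if n_prot > 0:
        g = int(np.ceil(np.sqrt(n_prot)))
        spacing = p.patch_nm / g
        if spacing < 2 * FOOTPRINT_RADIUS + 0.5:
            raise ValueError("patch too small for the protein footprints")
        gx, gy = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        grid = (np.stack([gx, gy], axis=-1).reshape(-1, 2)[:n_prot] + 0.5) * spacing
    else:
        grid = np.zeros((0, 2))
    theta0 = rng.uniform(-np.pi, np.pi, size=n_prot)
    if p.initial_orientations is not None:
        if len(p.initial_orientations) != n_prot:
            raise ValueError("initial_orientations must list one angle per protein")
        theta0 = np.asarray(p.initial_orientations, dtype=float).copy()
    if p.conformations == "mixed":
        conf = np.array(["inactive"] * n_prot, dtype=object)
        conf[rng.permutation(n_prot)[: n_prot // 2]] = "active"
    elif p.conformations in ("inactive", "active"):
        conf = np.array([p.conformations] * n_prot, dtype=object)
    else:
        raise ValueError(f"unknown conformation assignment {p.conformations!r}")

    # planted bonds: pose the bound protomers deterministically
    bound_pose = _solve_planted_bonds(p, grid, theta0)
    for pid, (xy, th) in bound_pose.items():
        grid[pid] = xy
        theta0[pid] = th

    # lipid counts per leaflet and species
    area = p.patch_nm ** 2
    n_upper = int(round(area * p.lipid_density_upper))
    n_lower = int(round(area * p.lipid_density_lower))
    upper_counts = _largest_remainder_counts(p.upper_composition, n_upper)
    lower_counts = _largest_remainder_counts(p.lower_composition, n_lower)

    species: list[LipidSpecies] = []
    sp_index: dict[tuple[str, int], int] = {}
    lip_species, lip_leaflet = [], []
    for leaflet, counts in ((1, upper_counts), (-1, lower_counts)):
        for cls_name, cnt in counts.items():
            if cnt == 0:
                continue
            key = (cls_name, leaflet)
            if key not in sp_index:
                sp_index[key] = len(species)
                species.append(default_species(leaflet, cls_name))
            lip_species.extend([sp_index[key]] * cnt)
            lip_leaflet.extend([leaflet] * cnt)
    lip_species = np.array(lip_species, dtype=int)
    lip_leaflet = np.array(lip_leaflet, dtype=int)
    n_lip = len(lip_species)

    # lipid placement: uniform outside footprints; SM tilted toward order
    centers, amps = b.field_centers(grid, theta0)
    is_sm = np.array([species[s].headgroup_class == "SM" for s in lip_species])
    xy = np.empty((n_lip, 2))
    n_cand = 64  # importance resampling pool for the SM order tilt
    for i in range(n_lip):
        for attempt in range(200):
            if is_sm[i] and p.sm_coupling > 0:
                cands = rng.uniform(0, p.patch_nm, size=(n_cand, 2))
                if n_prot:
                    d = cands[:, None, :] - grid[None, :, :]
                    d -= p.patch_nm * np.round(d / p.patch_nm)
                    ok = (d ** 2).sum(axis=-1).min(axis=1) >= FOOTPRINT_RADIUS ** 2
                    cands = cands[ok]
                if len(cands) == 0:
                    continue
                m = b.order_mean_field(cands, centers, amps)
                logw = -p.sm_coupling * (m - p.baseline_chi) / 0.1
                w = np.exp(logw - logw.max())
                xy[i] = cands[rng.choice(len(cands), p=w / w.sum())]
                break
            cand = rng.uniform(0, p.patch_nm, size=2)
            if n_prot:
                d = cand - grid
                d -= p.patch_nm * np.round(d / p.patch_nm)
                if np.min((d ** 2).sum(axis=1)) < FOOTPRINT_RADIUS ** 2:
                    continue
            xy[i] = cand
            break
        else:
            raise ValueError("patch too small: could not place all lipids")

    # latent state
    m0 = b.order_mean_field(xy, centers, amps)
    chi = np.clip(m0 + p.chi_sd * rng.standard_normal(n_lip), 0.02, np.pi / 2 - 0.02)
    psi = rng.uniform(-np.pi, np.pi, n_lip)
    z_jitter = 0.05 * rng.standard_normal(n_lip)

    # assemble topology (proteins first, then lipids)
    proteins: list[ProteinTopology] = []
    bead_cursor = 0
    templates = {}
    for pid in range(n_prot):
        bb_t, sc_t, resnum, hmap = templates.setdefault(
            conf[pid], _protein_template(conf[pid]))
        n_res = len(resnum)
        bb_idx = bead_cursor + np.arange(n_res)
        sc_idx = [np.array([bead_cursor + n_res + r]) for r in range(n_res)]
        proteins.append(ProteinTopology(
            protein_id=pid, conformation=conf[pid], residue_numbers=resnum,
            bb_index=bb_idx, sc_indices=sc_idx, helix_map=dict(hmap)))
        bead_cursor += 2 * n_res
    first_bead = np.empty(n_lip, dtype=int)
    for i in range(n_lip):
        first_bead[i] = bead_cursor
        bead_cursor += species[lip_species[i]].n_beads
    topology = SystemTopology(
        species=species, lipid_species_index=lip_species,
        lipid_leaflet=lip_leaflet, lipid_first_bead=first_bead,
        proteins=proteins, box=b.box)

    state = _State(prot_xy=grid, prot_theta=theta0, conf=conf,
                   lip_xy=xy, chi=chi, psi=psi, z_jitter=z_jitter,
                   leaflet=lip_leaflet.astype(float).copy(),
                   transit=np.zeros(n_lip, dtype=int),
                   bound_with=_initial_bonds(p, n_prot),
                   builder=b, templates=templates)
    frame0 = TrajectoryFrame(0.0, _render(topology, state, centers, amps), b.box)
    state.frame0_cache = frame0
    topology._generator_state = state  # consumed by simulate()
    return topology, frame0


@dataclass
class _State:
    prot_xy: np.ndarray
    prot_theta: np.ndarray
    conf: np.ndarray
    lip_xy: np.ndarray
    chi: np.ndarray
    psi: np.ndarray
    z_jitter: np.ndarray
    leaflet: np.ndarray          # +1/-1, flips during transit completion
    transit: np.ndarray          # frames remaining in a flip transit (0 = none)
    bound_with: np.ndarray       # partner id or -1
    builder: _Builder
    templates: dict
    frame0_cache: object = None


def _initial_bonds(p: GeneratorParams, n_prot: int) -> np.ndarray:
    bound = np.full(n_prot, -1, dtype=int)
    for i, j, _ in p.planted_bonds:
        bound[i] = j if bound[i] == -1 else bound[i]
        bound[j] = i if bound[j] == -1 else bound[j]
    return bound


def _solve_planted_bonds(p: GeneratorParams, grid: np.ndarray, theta: np.ndarray):
    """Deterministic poses realizing the planted bonds (chains allowed)."""
    placed: dict[int, tuple[np.ndarray, float]] = {}
    for i, j, spec_idx in p.planted_bonds:
        spec = p.interface_library[spec_idx]
        if i not in placed:
            u = np.array([1.0, 0.0])
            placed[i] = (grid[i].copy(), float(spec.alpha0))
        xy_i, th_i = placed[i]
        ang_u = th_i - spec.alpha0
        u = np.array([np.cos(ang_u), np.sin(ang_u)])
        xy_j = xy_i + spec.bound_distance * u
        th_j = (ang_u + np.pi) + spec.beta0
        placed[j] = (xy_j, float(th_j))
    return placed


def _render(topology: SystemTopology, state: _State, centers, amps) -> np.ndarray:
    """All bead positions from the current latent state."""
    b = state.builder
    p = b.p
    pos = np.empty((topology.n_beads, 3))
    for pid, prot in enumerate(topology.proteins):
        bb_t, sc_t, _, _ = state.templates[state.conf[pid]]
        th = state.prot_theta[pid]
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        shift = np.array([state.prot_xy[pid][0], state.prot_xy[pid][1], 0.0])
        pos[prot.bb_index] = bb_t @ R.T + shift
        sc_flat = sc_t @ R.T + shift
        for r, idx in enumerate(prot.sc_indices):
            pos[idx] = sc_flat[r]
    # lipids: z of the reference bead from leaflet, transit, and the field
    m = b.order_mean_field(state.lip_xy, centers, amps)
    flip_capable = np.array([topology.species[si].flip_capable
                             for si in topology.lipid_species_index])
    base = np.where(flip_capable, FLIP_REF_Z, LINKER_Z)
    depth = np.where(flip_capable, 0.0,
                     p.thickness_order_coupling * (p.baseline_chi - m))
    z_rest = state.leaflet * (base + depth) + state.z_jitter
    z_ref = z_rest.copy()
    in_transit = state.transit > 0
    if np.any(in_transit):
        T = p.flip_transit_frames
        # leaflet already holds the destination; z walks from the origin side
        # through the midplane, arriving when transit hits 0.  Intermediate
        # waypoints are compressed well inside the middle zone so instantaneous
        # midplane fluctuations cannot shift the committed crossing frame.
        frac = (T - state.transit[in_transit] + 1) / (T + 1.0)
        origin = -state.leaflet[in_transit]
        z_ref[in_transit] = 0.45 * origin * base[in_transit] * (1 - 2 * frac)
    for si, sp in enumerate(topology.species):
        ids = np.nonzero(topology.lipid_species_index == si)[0]
        if len(ids) == 0:
            continue
        beads = b.lipid_beads(sp, state.lip_xy[ids], z_ref[ids],
                              state.chi[ids], state.psi[ids])
        for k, i in enumerate(ids):
            pos[topology.lipid_bead_slice(i)] = beads[k]
    return pos


def simulate(topology: SystemTopology, frame0: TrajectoryFrame,
             params: GeneratorParams):
    """Propagate the system and return (Trajectory, GroundTruth).

    Dynamics per frame (stride dt): Brownian lipid xy steps (sphingomyelin
    with a Metropolis tilt toward ordered regions, all species excluded from
    protein footprints); mean-reverting order angles around the planted field;
    scheduled Poisson flip events with a linear z transit; rigid protomer
    diffusion/rotation with capture-window binding at the planted interfaces.
    """
    p = params
    if p.n_frames <= 0:
        raise ValueError("zero frames requested")
    state0: _State = getattr(topology, "_generator_state", None)
    if state0 is None:
        raise ValueError("topology was not produced by build_system")
    state = _State(
        prot_xy=state0.prot_xy.copy(), prot_theta=state0.prot_theta.copy(),
        conf=state0.conf, lip_xy=state0.lip_xy.copy(), chi=state0.chi.copy(),
        psi=state0.psi.copy(), z_jitter=state0.z_jitter,
        leaflet=state0.leaflet.copy(), transit=state0.transit.copy(),
        bound_with=state0.bound_with.copy(), builder=state0.builder,
        templates=state0.templates)
    b = state.builder
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    dt = p.stride_ns
    n_lip = topology.n_lipids
    n_prot = len(topology.proteins)

    flip_capable = np.array([topology.species[si].flip_capable
                             for si in topology.lipid_species_index])
    cls_of = np.array([topology.species[si].headgroup_class
                       for si in topology.lipid_species_index], dtype=object)
    rate_ns = np.zeros(n_lip)
    for cls_name, r in p.flip_rates_per_s.items():
        rate_ns[cls_of == cls_name] = r * 1e-9
    rate_ns[~flip_capable] = 0.0

    # pre-draw flip schedules (continuous event times, per molecule)
    total_t = p.n_frames * dt
    schedules: dict[int, list[float]] = {}
    for i in np.nonzero(rate_ns > 0)[0]:
        t, events = 0.0, []
        while True:
            t += rng.exponential(1.0 / rate_ns[i])
            if t >= total_t:
                break
            events.append(t)
        if events:
            schedules[int(i)] = events
    sched_ptr = {i: 0 for i in schedules}

    is_sm = cls_of == "SM"
    sigma_lip = np.sqrt(2 * p.d_lipid_nm2_ns * dt)
    sigma_prot = np.sqrt(2 * p.d_protein_nm2_ns * dt)
    sigma_rot = np.sqrt(2 * p.d_rot_rad2_ns * dt)
    sigma_psi = np.sqrt(2 * p.psi_d_rad2_ns * dt)
    L = p.patch_nm

    positions = np.empty((p.n_frames, topology.n_beads, 3), dtype=np.float32)
    times = dt * np.arange(p.n_frames)
    chi_series = (np.empty((p.n_frames, n_lip), dtype=np.float32)
                  if p.store_chi else None)
    flip_rows = []
    open_eps: dict[tuple[int, int], dict] = {}
    closed_eps: list[dict] = []
    for i, j, k in p.planted_bonds:
        key = (min(i, j), max(i, j))
        open_eps[key] = {"i": key[0], "j": key[1],
                         "interface": p.interface_library[k].name,
                         "spec": None, "frame_start": 0}
    permanently_bound = _permanent(state, p)

    centers, amps = b.field_centers(state.prot_xy, state.prot_theta)
    base_z = np.where(flip_capable, FLIP_REF_Z, LINKER_Z)

    for f in range(p.n_frames):
        t_now = f * dt
        # --- lipid lateral moves ------------------------------------------
        if sigma_lip > 0:
            prop = state.lip_xy + sigma_lip * rng.standard_normal((n_lip, 2))
            prop = np.mod(prop, L)
            accept = np.ones(n_lip, dtype=bool)
            if n_prot:
                d = prop[:, None, :] - state.prot_xy[None, :, :]
                d -= L * np.round(d / L)
                new_d2 = (d ** 2).sum(axis=-1).min(axis=1)
                d0 = state.lip_xy[:, None, :] - state.prot_xy[None, :, :]
                d0 -= L * np.round(d0 / L)
                old_d2 = (d0 ** 2).sum(axis=-1).min(axis=1)
                # stay out of footprints; a lipid caught inside one when a
                # binding event snapped the protomers may still step outward
                accept &= (new_d2 >= FOOTPRINT_RADIUS ** 2) | (new_d2 >= old_d2)
            if p.sm_coupling > 0 and np.any(is_sm):
                m_old = b.order_mean_field(state.lip_xy[is_sm], centers, amps)
                m_new = b.order_mean_field(prop[is_sm], centers, amps)
                logw = -p.sm_coupling * (m_new - m_old) / 0.1
                accept[is_sm] &= np.log(rng.random(is_sm.sum())) < logw
            state.lip_xy[accept] = prop[accept]
        # --- order angles --------------------------------------------------
        if p.chi_sd > 0 or p.chi_relax_ns > 0:
            m = b.order_mean_field(state.lip_xy, centers, amps)
            if p.chi_sd > 0:
                a = dt / max(p.chi_relax_ns, dt)
                noise = p.chi_sd * np.sqrt(2 * a) * rng.standard_normal(n_lip)
                state.chi = state.chi + a * (m - state.chi) + noise
                state.chi = np.clip(state.chi, 0.02, np.pi / 2 - 0.02)
        if sigma_psi > 0:
            state.psi = state.psi + sigma_psi * rng.standard_normal(n_lip)
        # --- flips ----------------------------------------------------------
        prev_transit = state.transit.copy()
        state.transit = np.maximum(state.transit - 1, 0)
        for i, ev in schedules.items():
            k = sched_ptr[i]
            if k < len(ev) and ev[k] <= t_now + dt:
                # defer until the transit completed AND one rest frame rendered
                # (frame 0 included), so every logged flip is a committed
                # leaflet change the detector can also see
                if prev_transit[i] > 0 or f == 0:
                    continue
                sched_ptr[i] = k + 1
                direction = "up->down" if state.leaflet[i] > 0 else "down->up"
                state.leaflet[i] = -state.leaflet[i]
                state.transit[i] = p.flip_transit_frames
                # the detector commits the event when z enters the far head
                # zone; with a linear transit that is the final transit frame
                commit = f + p.flip_transit_frames
                if commit < p.n_frames:
                    flip_rows.append((int(i), cls_of[i], int(commit),
                                      float(ev[k]), direction))
        # --- proteins -------------------------------------------------------
        if n_prot:
            free = np.array([state.bound_with[j] < 0 and j not in permanently_bound
                             for j in range(n_prot)])
            if sigma_prot > 0 and np.any(free):
                state.prot_xy[free] += sigma_prot * rng.standard_normal((free.sum(), 2))
                state.prot_xy[free] = np.mod(state.prot_xy[free], L)
            if sigma_rot > 0 and np.any(free):
                state.prot_theta[free] += sigma_rot * rng.standard_normal(free.sum())
            _try_bind_unbind(state, p, rng, f, open_eps, closed_eps)
            centers, amps = b.field_centers(state.prot_xy, state.prot_theta)
        positions[f] = _render(topology, state, centers, amps)
        if chi_series is not None:
            chi_series[f] = state.chi
    # close episodes still open at the last frame
    for e in open_eps.values():
        e["frame_end"] = p.n_frames - 1
        closed_eps.append(e)
    ep_rows = [(e["i"], e["j"], e["interface"], e["frame_start"], e["frame_end"])
               for e in closed_eps]
    truth = GroundTruth(
        params=p,
        flip_events=pd.DataFrame(
            flip_rows, columns=["molecule", "species", "frame", "time_ns", "direction"]),
        dimer_episodes=pd.DataFrame(
            ep_rows, columns=["protein_i", "protein_j", "interface",
                              "frame_start", "frame_end"]),
        chi_series=chi_series,
    )
    traj = Trajectory(times=times, positions=positions.astype(np.float64),
                      box=b.box, topology=topology)
    return traj, truth


def _try_bind_unbind(state: _State, p: GeneratorParams, rng, frame: int,
                     open_eps: dict, closed_eps: list) -> None:
    n_prot = len(state.prot_xy)
    L = p.patch_nm
    # unbinding
    for i in range(n_prot):
        j = state.bound_with[i]
        if j > i:
            spec = open_eps.get((i, j), {}).get("spec")
            k_off = spec.k_off_per_ns if spec else 0.0
            if k_off > 0 and rng.random() < 1 - np.exp(-k_off * p.stride_ns):
                state.bound_with[i] = state.bound_with[j] = -1
                ep = open_eps.pop((i, j))
                ep["frame_end"] = frame
                closed_eps.append(ep)
    # binding
    for i in range(n_prot):
        if state.bound_with[i] >= 0 or i in _permanent(state, p):
            continue
        for j in range(i + 1, n_prot):
            if state.bound_with[j] >= 0 or j in _permanent(state, p):
                continue
            d = state.prot_xy[j] - state.prot_xy[i]
            d -= L * np.round(d / L)
            r = np.hypot(d[0], d[1])
            if r == 0:
                continue
            ang_u = np.arctan2(d[1], d[0])
            for spec in p.interface_library:
                if r > spec.capture_radius:
                    continue
                alpha = _wrap(state.prot_theta[i] - ang_u)
                beta = _wrap(state.prot_theta[j] - (ang_u + np.pi))
                if (abs(_wrap(alpha - spec.alpha0)) > spec.capture_half_width or
                        abs(_wrap(beta - spec.beta0)) > spec.capture_half_width):
                    continue
                if rng.random() < 1 - np.exp(-spec.k_on_per_ns * p.stride_ns):
                    u = d / r
                    mid = state.prot_xy[i] + d / 2
                    state.prot_xy[i] = np.mod(mid - u * spec.bound_distance / 2, L)
                    state.prot_xy[j] = np.mod(mid + u * spec.bound_distance / 2, L)
                    state.prot_theta[i] = ang_u + spec.alpha0
                    state.prot_theta[j] = (ang_u + np.pi) + spec.beta0
                    state.bound_with[i] = j
                    state.bound_with[j] = i
                    open_eps[(i, j)] = {"i": i, "j": j, "interface": spec.name,
                                        "spec": spec, "frame_start": frame}
                    break
            if state.bound_with[i] >= 0:
                break


def _permanent(state: _State, p: GeneratorParams) -> set:
    out = set()
    for i, j, _ in p.planted_bonds:
        out.update((i, j))
    return out


def _wrap(a: float) -> float:
    return (a + np.pi) % (2 * np.pi) - np.pi
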