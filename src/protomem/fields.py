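"""Gridded scalar fields in the membrane plane: order, thickness, density.

Two canonical grids appear throughout:

* order/thickness maps use square bins of side 0.175 nm (1.75 x 1.75 A^2);
* receptor-centered lipid density maps use 50 x 50 bins of side 0.2 nm.

A ``ScalarField2D`` is an accumulator (per-bin value sum + sample count) in
one of two modes: ``mean-field`` (report per-bin means, empty bins are
*missing*, never zero) or ``normalized-density`` (report per-bin probability,
summing to 1 over occupied bins).  Samples falling outside the grid are
wrapped by xy periodicity, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .order import lipid_order_samples

ORDER_BIN_NM = 0.175     #: side of the order/thickness grid bins (nm)
DENSITY_BIN_NM = 0.2     #: side of the density grid bins (nm)
DENSITY_N_BINS = 50      #: density maps are 50 x 50


class GridMismatchError(ValueError):
    pass


@dataclass
class ScalarField2D:
    origin: np.ndarray          # (2,) nm, lower-left corner
    bin_size: float             # nm, square bins
    shape: tuple[int, int]
    mode: str = "mean-field"    # or "normalized-density"
    value_sum: np.ndarray = field(default=None)
    count: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.mode not in ("mean-field", "normalized-density"):
            raise ValueError(f"unknown field mode {self.mode!r}")
        if self.value_sum is None:
            self.value_sum = np.zeros(self.shape)
        if self.count is None:
            self.count = np.zeros(self.shape, dtype=float)

    # -- constructors ------------------------------------------------------
    @classmethod
    def for_box(cls, box, bin_size: float = ORDER_BIN_NM, mode="mean-field"):
        """Grid covering the full periodic box (origin at 0)."""
        shape = (int(np.ceil(box[0] / bin_size)), int(np.ceil(box[1] / bin_size)))
        return cls(np.zeros(2), bin_size, shape, mode)

    @classmethod
    def centered(cls, n_bins: int = DENSITY_N_BINS, bin_size: float = DENSITY_BIN_NM,
                 mode="normalized-density"):
        """Grid centered on the origin (receptor-centered maps)."""
        half = n_bins * bin_size / 2.0
        return cls(np.array([-half, -half]), bin_size, (n_bins, n_bins), mode)

    @classmethod
    def from_values(cls, template: "ScalarField2D", values: np.ndarray,
                    valid: np.ndarray) -> "ScalarField2D":
        """Derived mean-field on the same grid (e.g. a thickness difference)."""
        out = cls(template.origin.copy(), template.bin_size, template.shape, "mean-field")
        out.value_sum = np.where(valid, values, 0.0)
        out.count = valid.astype(float)
        return out

    # -- geometry ----------------------------------------------------------
    @property
    def extent(self) -> np.ndarray:
        return np.array(self.shape) * self.bin_size

    def bin_indices(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin of each xy sample; out-of-grid samples wrap periodically."""
        rel = (np.atleast_2d(xy) - self.origin) / self.bin_size
        ix = np.mod(np.floor(rel[:, 0]).astype(int), self.shape[0])
        iy = np.mod(np.floor(rel[:, 1]).astype(int), self.shape[1])
        return ix, iy

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.origin[0] + (np.arange(self.shape[0]) + 0.5) * self.bin_size
        cy = self.origin[1] + (np.arange(self.shape[1]) + 0.5) * self.bin_size
        return cx, cy

    # -- accumulation ------------------------------------------------------
    def add(self, xy: np.ndarray, values: np.ndarray | None = None) -> None:
        xy = np.atleast_2d(xy)
        if len(xy) == 0:
            return
        ix, iy = self.bin_indices(xy)
        np.add.at(self.count, (ix, iy), 1.0)
        if values is not None:
            np.add.at(self.value_sum, (ix, iy), np.asarray(values, dtype=float))
        elif self.mode == "mean-field":
            raise ValueError("mean-field accumulation requires values")

    # -- results -----------------------------------------------------------
    def mean(self) -> np.ndarray:
        """Per-bin mean; empty bins are NaN (missing), never zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.value_sum / self.count, np.nan)

    def probability(self) -> np.ndarray:
        """Normalized per-bin probability (sums to 1 over occupied bins)."""
        total = self.count.sum()
        if total == 0:
            return np.zeros(self.shape)
        return self.count / total

    def occupied(self) -> np.ndarray:
        return self.count > 0

    def same_grid(self, other: "ScalarField2D") -> bool:
        return (self.shape == other.shape and self.bin_size == other.bin_size
                and np.allclose(self.origin, other.origin))

    # -- matrix-text I/O ---------------------------------------------------
    def save_text(self, path) -> None:
        """Dense matrix text with a 3-line header (origin, bin size, shape/mode)."""
        data = self.mean() if self.mode == "mean-field" else self.probability()
        header = (f"origin_nm {self.origin[0]:.6f} {self.origin[1]:.6f}\n"
                  f"bin_nm {self.bin_size:.6f}\n"
                  f"shape {self.shape[0]} {self.shape[1]} mode {self.mode}")
        np.savetxt(path, data, header=header, comments="# ")

    @classmethod
    def load_text(cls, path) -> "ScalarField2D":
        with open(path) as fh:
            head = [fh.readline() for _ in range(3)]
        origin = np.array([float(v) for v in head[0].split()[2:4]])
        bin_size = float(head[1].split()[2])
        parts = head[2].split()
        shape = (int(parts[2]), int(parts[3]))
        mode = parts[5]
        data = np.loadtxt(path)
        data = data.reshape(shape)
        out = cls(origin, bin_size, shape, mode)
        if mode == "mean-field":
            valid = ~np.isnan(data)
            out.value_sum = np.where(valid, data, 0.0)
            out.count = valid.astype(float)
        else:
            out.count = data
        return out


def accumulate_field(xy, values, grid: ScalarField2D) -> ScalarField2D:
    """Accumulate scalar samples into a mean-field grid (in place, returned)."""
    grid.add(np.asarray(xy), np.asarray(values))
    return grid


def order_field(traj, topology, bin_size: float = ORDER_BIN_NM,
                grid: ScalarField2D | None = None) -> ScalarField2D:
    """Mean lipid order chi on the standard grid, non-flipping lipids only."""
    if grid is None:
        grid = ScalarField2D.for_box(traj.box, bin_size)
    for i in range(traj.n_frames):
        s = lipid_order_samples(traj.positions[i], topology, frame_index=i)
        grid.add(s.xy, s.chi)
    return grid


def thickness_map(traj, topology, bin_size: float = ORDER_BIN_NM,
                  grid: ScalarField2D | None = None) -> ScalarField2D:
    """Local bilayer thickness on the order grid.

    Per bin: (mean z of upper-leaflet first-linker beads) minus (mean z of the
    lower-leaflet ones), averaged over frames; only the non-flipping species
    enter, and the leaflet is assigned per frame by the reference bead's side
    of the instantaneous midplane.  Bins missing either leaflet are missing.
    """
    from .trajectory import bilayer_midplane

    if grid is None:
        grid = ScalarField2D.for_box(traj.box, bin_size)
    upper = ScalarField2D(grid.origin.copy(), grid.bin_size, grid.shape)
    lower = ScalarField2D(grid.origin.copy(), grid.bin_size, grid.shape)
    ids = topology.non_flipping_lipids()
    refs = topology.reference_bead_indices(ids)
    for i in range(traj.n_frames):
        pos = traj.positions[i]
        mid = bilayer_midplane(topology, pos)
        z = pos[refs, 2]
        up = z >= mid
        upper.add(pos[refs[up], :2], z[up])
        lower.add(pos[refs[~up], :2], z[~up])
    valid = upper.occupied() & lower.occupied()
    thickness = np.where(valid, upper.mean() - lower.mean(), 0.0)
    return ScalarField2D.from_values(grid, thickness, valid)


def order_distribution(chi_by_replica: list[np.ndarray], n_bins: int = 64
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized histograms of chi per replica plus their average.

    Returns (edges, per_replica (R, n_bins), mean (n_bins,)); each histogram
    integrates to 1 over [0, pi/2].
    """
    edges = np.linspace(0.0, np.pi / 2, n_bins + 1)
    hists = np.stack([np.histogram(chi, bins=edges, density=True)[0]
                      for chi in chi_by_replica])
    return edges, hists, hists.mean(axis=0)


def thickness_order_correlation(order_fld: ScalarField2D,
                                thickness_fld: ScalarField2D
                                ) -> tuple[pd.DataFrame, float]:
    """Paired per-bin (order, thickness) table and their Pearson r.

    Only bins occupied in both fields enter; with fewer than two such bins the
    correlation is undefined and reported as NaN.
    """
    if not order_fld.same_grid(thickness_fld):
        raise GridMismatchError("order and thickness fields live on different grids")
    both = order_fld.occupied() & thickness_fld.occupied()
    ix, iy = np.nonzero(both)
    table = pd.DataFrame({
        "ix": ix, "iy": iy,
        "order": order_fld.mean()[ix, iy],
        "thickness": thickness_fld.mean()[ix, iy],
    })
    if len(table) < 2 or table["order"].std() == 0 or table["thickness"].std() == 0:
        return table, float("nan")
    r = stats.pearsonr(table["order"], table["thickness"]).statistic
    return table, float(r)


def sm_order_enrichment(traj, topology, bin_size: float = ORDER_BIN_NM
                        ) -> pd.DataFrame:
    """Per-species probability of sitting in ordered vs disordered regions.

    The order field (non-flipping lipids) is computed on the standard grid;
    the global mean chi over all samples splits the bins into an ordered side
    (chi below the mean) and a disordered side.  For each headgroup class the
    table reports the fraction of its reference-bead samples falling on each
    side; the two fractions sum to 1.  In an uncoupled membrane every species
    sits near 50/50; sphingomyelin enrichment of ordered regions shows up as
    ``p_ordered`` > 0.5.
    """
    grid = order_field(traj, topology, bin_size)
    mean_fld = grid.mean()
    global_mean = grid.value_sum.sum() / grid.count.sum()
    ordered_side = mean_fld < global_mean  # NaN compares False -> handled below
    occupied = grid.occupied()

    rows = {}
    classes = sorted({sp.headgroup_class for sp in topology.species})
    for cls_name in classes:
        ids = topology.lipids_of_class(cls_name)
        if len(ids) == 0:
            continue
        refs = topology.reference_bead_indices(ids)
        n_ord = n_tot = 0
        for i in range(traj.n_frames):
            xy = traj.positions[i][refs, :2]
            bx, by = grid.bin_indices(xy)
            in_field = occupied[bx, by]
            n_tot += int(in_field.sum())
            n_ord += int((ordered_side[bx, by] & in_field).sum())
        if n_tot == 0:
            continue
        p_ord = n_ord / n_tot
        rows[cls_name] = {"p_ordered": p_ord, "p_disordered": 1.0 - p_ord,
                          "n_samples": n_tot}
    return pd.DataFrame.from_dict(rows, orient="index")
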