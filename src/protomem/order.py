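"""Per-lipid order parameter and cholesterol orientation.

The order metric is the folded angle chi in [0, pi/2] between the membrane
normal (z) and the vector from a tail's linker bead (GL1/GL2 or AM1/AM2) to
its terminal bead; for cholesterol the vector runs from the ROH bead to the
final bead.  chi = 0 is a fully ordered tail parallel to the normal; pi/2 a
tail lying flat in the membrane plane.  Folding (|v_z|) makes the two leaflets
share one scale.

This metric deliberately replaces the traditional P2 segmental order
parameter: it is cheap and applies unchanged to sterols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import min_image_displacement

logger = logging.getLogger(__name__)

#: Half-width (nm) of the bilayer middle zone (full width 1.6 nm).
MIDDLE_ZONE_HALF_WIDTH = 0.8

ZONE_UPPER, ZONE_MIDDLE, ZONE_LOWER = "upper-head", "middle", "lower-head"


@dataclass
class OrderSamples:
    """Flat arrays of per-tail order samples (one row per tail per lipid)."""

    mol_id: np.ndarray
    tail_id: np.ndarray           # 1 or 2; sterols have a single pseudo-tail 1
    chi: np.ndarray               # radians in [0, pi/2]
    xy: np.ndarray                # reference-bead position, (n, 2)
    frame: np.ndarray
    zone: np.ndarray | None = None  # cholesterol only

    def __len__(self) -> int:
        return len(self.chi)

    @staticmethod
    def concatenate(parts: list["OrderSamples"]) -> "OrderSamples":
        parts = [p for p in parts if len(p)]
        if not parts:
            return OrderSamples(*(np.empty(0) for _ in range(3)),
                                np.empty((0, 2)), np.empty(0))
        zone = None
        if parts[0].zone is not None:
            zone = np.concatenate([p.zone for p in parts])
        return OrderSamples(
            np.concatenate([p.mol_id for p in parts]),
            np.concatenate([p.tail_id for p in parts]),
            np.concatenate([p.chi for p in parts]),
            np.concatenate([p.xy for p in parts]),
            np.concatenate([p.frame for p in parts]),
            zone,
        )


def order_angle(vectors: np.ndarray) -> np.ndarray:
    """Folded angle chi = arccos(|v_z| / ||v||), invariant under v -> -v."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norm = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore"):
        cos = np.abs(v[..., 2]) / norm
    return np.arccos(np.clip(cos, 0.0, 1.0))


def lipid_order_samples(positions, topology, frame_index: int = 0,
                        lipid_ids=None, exclude_flip_capable: bool = True) -> OrderSamples:
    """One order sample per tail per lipid from a single frame.

    By default the flip-flopping species (CHOL, CER, DAG) are excluded, as the
    field maps average over the non-flipping lipids only; pass
    ``exclude_flip_capable=False`` to keep them.
    """
    if lipid_ids is None:
        lipid_ids = (topology.non_flipping_lipids() if exclude_flip_capable
                     else np.arange(topology.n_lipids))
    lipid_ids = np.asarray(lipid_ids, dtype=int)
    mol, tail, chi, xy = [], [], [], []
    for sp_idx in np.unique(topology.lipid_species_index[lipid_ids]):
        sp = topology.species[sp_idx]
        ids = lipid_ids[topology.lipid_species_index[lipid_ids] == sp_idx]
        if exclude_flip_capable and sp.flip_capable:
            continue
        if not sp.tails:
            logger.warning("species %s has no tails; skipped", sp.name)
            continue
        first = topology.lipid_first_bead[ids]
        ref = positions[first + sp.reference_bead, :2]
        for t, (a, b) in enumerate(sp.tails, start=1):
            # min-image: a molecule straddling the box edge keeps a short tail
            v = min_image_displacement(positions[first + a],
                                       positions[first + b], topology.box)
            mol.append(ids)
            tail.append(np.full(len(ids), t))
            chi.append(order_angle(v))
            xy.append(ref)
    if not mol:
        return OrderSamples(np.empty(0, int), np.empty(0, int), np.empty(0),
                            np.empty((0, 2)), np.empty(0, int))
    mol_arr = np.concatenate(mol)
    return OrderSamples(mol_arr, np.concatenate(tail).astype(int),
                        np.concatenate(chi), np.concatenate(xy),
                        np.full(len(mol_arr), frame_index))


def chol_zone(z_relative: np.ndarray) -> np.ndarray:
    """Three-zone split of the bilayer by ROH height above the midplane.

    The middle of the bilayer is 1.6 nm thick, so the middle zone is
    |z| < 0.8 nm; above/below is the upper/lower headgroup region.
    """
    z = np.asarray(z_relative, dtype=float)
    zone = np.where(np.abs(z) < MIDDLE_ZONE_HALF_WIDTH, ZONE_MIDDLE,
                    np.where(z > 0, ZONE_UPPER, ZONE_LOWER))
    return zone


def chol_order_samples(positions, topology, midplane: float,
                       frame_index: int = 0) -> OrderSamples:
    """Cholesterol orientation samples with the head/middle zone label."""
    ids = topology.lipids_of_class("CHOL")
    if len(ids) == 0:
        return OrderSamples(np.empty(0, int), np.empty(0, int), np.empty(0),
                            np.empty((0, 2)), np.empty(0, int), np.empty(0, "U10"))
    sp = topology.species[topology.lipid_species_index[ids[0]]]
    first = topology.lipid_first_bead[ids]
    a, b = sp.tails[0]
    v = min_image_displacement(positions[first + a], positions[first + b],
                               topology.box)
    roh = positions[first + sp.reference_bead]
    return OrderSamples(ids, np.ones(len(ids), int), order_angle(v),
                        roh[:, :2], np.full(len(ids), frame_index),
                        chol_zone(roh[:, 2] - midplane))
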