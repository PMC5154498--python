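"""Periodic geometry in an orthorhombic, xy-periodic box.

The membrane plane (x, y) is periodic; z never is.  All distances are nm.
"""

from __future__ import annotations

import numpy as np

#: Default periodicity: membrane plane only.
XY_PERIODIC = (True, True, False)


def min_image_displacement(p, q, box, periodic=XY_PERIODIC) -> np.ndarray:
    """Minimum-image displacement vector(s) from ``p`` to ``q``.

    Broadcasts over leading axes; only the axes flagged periodic are wrapped.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = q - p
    for ax in range(3):
        if periodic[ax]:
            d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def min_image_distance(p, q, box, periodic=XY_PERIODIC) -> np.ndarray:
    return np.linalg.norm(min_image_displacement(p, q, box, periodic), axis=-1)


def wrap_positions(pos, box, periodic=XY_PERIODIC) -> np.ndarray:
    """Wrap coordinates of periodic axes into [0, L)."""
    pos = np.array(pos, dtype=float)
    for ax in range(3):
        if periodic[ax]:
            pos[..., ax] = np.mod(pos[..., ax], box[ax])
    return pos


def unwrap_about(pos, anchor, box, periodic=XY_PERIODIC) -> np.ndarray:
    """Shift each position by whole boxes so it is the image nearest ``anchor``."""
    pos = np.asarray(pos, dtype=float)
    return np.asarray(anchor, dtype=float) + min_image_displacement(anchor, pos, box, periodic)


def center_of_mass(positions, box=None, periodic=XY_PERIODIC) -> np.ndarray:
    """Unweighted mean of bead positions, minimum-image consistent.

    Coarse-grained beads are treated as equal mass.  When a periodic ``box``
    is given the selection is unwrapped about its first bead before averaging,
    so a molecule straddling a boundary gets a physically sensible center.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] == 0:
        raise ValueError("center_of_mass needs a non-empty (n, 3) selection")
    if box is None:
        return positions.mean(axis=0)
    unwrapped = unwrap_about(positions, positions[0], box, periodic)
    com = unwrapped.mean(axis=0)
    return wrap_positions(com, np.asarray(box, dtype=float), periodic)


def point_segment_distance_xy(points, a, b) -> np.ndarray:
    """Perpendicular (in-plane) distance from points to the segment a-b.

    Used by the pair-profile occlusion filter; operates on already-unwrapped
    xy coordinates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    a = np.asarray(a, dtype=float)[:2]
    b = np.asarray(b, dtype=float)[:2]
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)
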