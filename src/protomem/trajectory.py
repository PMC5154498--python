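"""Trajectory containers and multi-frame storage.

Two on-disk forms are supported: concatenated GRO frames (text) and a flat
binary *frame stack* — a single JSON header line followed by raw little-endian
float32 positions, frame-major.  The frame stack is the contractual format for
large runs; the writer emits only that form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import XY_PERIODIC
from .gro import GroFrame, parse_gro_block

_MAGIC = "protomem-frame-stack"


@dataclass
class TrajectoryFrame:
    """One frame: bead positions (nm), box lengths (nm), time (ns)."""

    time: float
    positions: np.ndarray
    box: np.ndarray
    periodic: tuple[bool, bool, bool] = XY_PERIODIC

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("frame holds non-finite coordinates")


@dataclass
class Trajectory:
    """Uniform-stride stack of frames sharing one topology.

    Positions are stored as a single (n_frames, n_beads, 3) array; ``frame(i)``
    returns a lightweight view.
    """

    times: np.ndarray            # (n_frames,) ns
    positions: np.ndarray        # (n_frames, n_beads, 3) nm
    box: np.ndarray              # (3,) nm
    replica_id: int = 0
    topology: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame stride must be constant")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    @property
    def stride(self) -> float:
        """Frame stride in ns (0 for a single-frame trajectory)."""
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    def frame(self, i: int) -> TrajectoryFrame:
        return TrajectoryFrame(float(self.times[i]), self.positions[i], self.box)

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- frame-stack I/O ---------------------------------------------------
    def save_frame_stack(self, path) -> None:
        header = {
            "format": _MAGIC,
            "version": 1,
            "n_frames": int(self.n_frames),
            "n_beads": int(self.n_beads),
            "dtype": "<f4",
            "box_nm": self.box.tolist(),
            "t0_ns": float(self.times[0]) if self.n_frames else 0.0,
            "stride_ns": self.stride,
            "replica_id": int(self.replica_id),
        }
        with open(path, "wb") as fh:
            fh.write((json.dumps(header) + "\n").encode())
            fh.write(np.ascontiguousarray(self.positions, dtype="<f4").tobytes())

    @classmethod
    def load_frame_stack(cls, path, topology=None) -> "Trajectory":
        with open(path, "rb") as fh:
            header = json.loads(fh.readline().decode())
            if header.get("format") != _MAGIC:
                raise ValueError("not a protomem frame stack")
            n_f, n_b = header["n_frames"], header["n_beads"]
            data = np.frombuffer(fh.read(n_f * n_b * 3 * 4), dtype="<f4")
        if data.size != n_f * n_b * 3:
            raise ValueError("frame stack truncated")
        times = header["t0_ns"] + header["stride_ns"] * np.arange(n_f)
        if n_f == 1:
            times = np.array([header["t0_ns"]])
        return cls(times=times, positions=data.reshape(n_f, n_b, 3).astype(float),
                   box=np.array(header["box_nm"]), replica_id=header.get("replica_id", 0),
                   topology=topology)


def read_gro_trajectory(path, stride_ns: float = 1.0, topology=None) -> Trajectory:
    """Read concatenated GRO frames (one file, frames back to back)."""
    frames: list[GroFrame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        _, fr, used = parse_gro_block(lines[i:], first_lineno=i + 1)
        frames.append(fr)
        i += used
    if not frames:
        raise ValueError("no frames found")
    pos = np.stack([f.positions for f in frames])
    times = stride_ns * np.arange(len(frames))
    return Trajectory(times=times, positions=pos, box=frames[0].box, topology=topology)


def bilayer_midplane(topology, positions) -> float:
    """Instantaneous midplane: mean z of all lipid reference beads (z = 0 datum)."""
    refs = topology.reference_bead_indices()
    if len(refs) == 0:
        return 0.0
    return float(np.mean(positions[refs, 2]))
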