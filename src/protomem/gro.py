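"""Fixed-width GRO coordinate files (nm, 3 decimals).

Velocities are ignored on read and never written.  Errors carry the 1-based
line number of the offending record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GroParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class GroFormatError(ValueError):
    pass


@dataclass
class GroRecord:
    """Names parsed from a GRO file (a topology fragment: no roles/helices)."""

    title: str
    residue_ids: np.ndarray
    residue_names: list[str]
    atom_names: list[str]


@dataclass
class GroFrame:
    positions: np.ndarray  # (n, 3) nm
    box: np.ndarray        # (3,) nm


def _parse_atom_line(line: str, lineno: int) -> tuple[int, str, str, tuple[float, float, float]]:
    if len(line.rstrip("\n")) < 44:
        raise GroParseError("truncated atom record (needs 44+ columns)", lineno)
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        atomname = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise GroParseError(f"malformed fixed-width field ({exc})", lineno) from None
    return resid, resname, atomname, (x, y, z)


def parse_gro_block(lines: list[str], first_lineno: int = 1) -> tuple[GroRecord, GroFrame, int]:
    """Parse one GRO frame from ``lines``; returns (record, frame, lines used).

    ``first_lineno`` is the 1-based file line number of ``lines[0]``, used in
    error messages.
    """
    if len(lines) < 2:
        raise GroFormatError("GRO file needs a title and an atom-count line")
    title = lines[0].rstrip("\n")
    try:
        n_atoms = int(lines[1])
    except ValueError:
        raise GroParseError("atom count is not an integer", first_lineno + 1) from None
    if len(lines) < 2 + n_atoms + 1:
        raise GroFormatError(
            f"missing box line: expected {n_atoms} atom records plus a box line"
        )
    resids = np.empty(n_atoms, dtype=int)
    resnames: list[str] = []
    atomnames: list[str] = []
    pos = np.empty((n_atoms, 3), dtype=float)
    for i in range(n_atoms):
        lineno = first_lineno + 2 + i
        resid, resname, atomname, xyz = _parse_atom_line(lines[2 + i], lineno)
        resids[i] = resid
        resnames.append(resname)
        atomnames.append(atomname)
        pos[i] = xyz
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise GroFormatError("box line must hold at least three lengths")
    try:
        box = np.array([float(v) for v in box_fields[:3]])
    except ValueError:
        raise GroParseError("malformed box line", first_lineno + 2 + n_atoms) from None
    return GroRecord(title, resids, resnames, atomnames), GroFrame(pos, box), 3 + n_atoms


def read_gro(path) -> tuple[GroRecord, GroFrame]:
    """Read one GRO frame; returns the name table and the coordinates."""
    with open(path) as fh:
        lines = fh.readlines()
    record, frame, _ = parse_gro_block(lines, first_lineno=1)
    return record, frame


def write_gro(path, positions, box, *, residue_ids=None, residue_names=None,
              atom_names=None, title: str = "protomem") -> None:
    """Write one GRO frame with 3-decimal nm positions."""
    positions = np.asarray(positions, dtype=float)
    if positions.size and not np.all(np.isfinite(positions)):
        raise GroFormatError("refusing to write non-finite positions")
    if positions.size and np.any(np.abs(positions) >= 10000):
        raise GroFormatError("position exceeds the 8.3f field width")
    n = len(positions)
    residue_ids = np.arange(1, n + 1) if residue_ids is None else residue_ids
    residue_names = ["MOL"] * n if residue_names is None else residue_names
    atom_names = ["BD"] * n if atom_names is None else atom_names
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write(f"{n:5d}\n")
        for i in range(n):
            fh.write(
                f"{int(residue_ids[i]) % 100000:5d}{residue_names[i][:5]:<5s}"
                f"{atom_names[i][:5]:>5s}{(i + 1) % 100000:5d}"
                f"{positions[i, 0]:8.3f}{positions[i, 1]:8.3f}{positions[i, 2]:8.3f}\n"
            )
        fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")
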