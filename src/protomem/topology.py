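"""System topology: lipid species, protein residue/helix maps, bead bookkeeping.

The coarse-grained representation follows the Martini conventions: one backbone
(BB) bead per protein residue plus optional sidechain (SC) beads; lipids are a
short list of named beads with roles (headgroup, linker, tail, tail-end,
sterol-hydroxyl).  Every lipid has exactly one *reference bead* used by all
spatial analyses: the sterol hydroxyl (ROH) for cholesterol, otherwise the
first linker bead (GL1 or AM1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

HEADGROUP_CLASSES = (
    "PC", "PE", "SM", "CHOL", "GM", "PS", "PI",
    "PIP1", "PIP2", "PIP3", "PA", "CER", "DAG", "LPC",
)

#: Lipid classes observed to traverse the bilayer (flip-flop).
FLIP_CAPABLE_CLASSES = frozenset({"CHOL", "CER", "DAG"})

BEAD_ROLES = ("headgroup", "linker", "tail", "tail-end", "sterol-hydroxyl")

HELIX_NAMES = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8")

#: Template helix -> inclusive residue-number range for the 65..352 construct.
DEFAULT_HELIX_MAP: dict[str, tuple[int, int]] = {
    "TM1": (65, 95),
    "TM2": (98, 128),
    "TM3": (131, 161),
    "TM4": (166, 196),
    "TM5": (201, 231),
    "TM6": (236, 266),
    "TM7": (271, 301),
    "H8": (306, 318),
}

FIRST_RESIDUE = 65
LAST_RESIDUE = 352


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species: bead layout, roles and leaflet of origin."""

    name: str
    headgroup_class: str
    charge: float
    leaflet: int  # +1 upper, -1 lower (leaflet of origin)
    bead_names: tuple[str, ...]
    bead_roles: tuple[str, ...]
    flip_capable: bool = False

    def __post_init__(self) -> None:
        if self.headgroup_class not in HEADGROUP_CLASSES:
            raise TopologyError(f"unknown headgroup class {self.headgroup_class!r}")
        if len(self.bead_names) != len(self.bead_roles):
            raise TopologyError(f"{self.name}: bead_names/bead_roles length mismatch")
        for role in self.bead_roles:
            if role not in BEAD_ROLES:
                raise TopologyError(f"{self.name}: unknown bead role {role!r}")
        if self.flip_capable and self.headgroup_class not in FLIP_CAPABLE_CLASSES:
            raise TopologyError(
                f"{self.name}: flip-capable lipids must be CHOL, CER or DAG"
            )
        # exactly one reference bead per molecule
        n_ref = self.bead_roles.count("sterol-hydroxyl")
        if n_ref == 0 and "linker" not in self.bead_roles:
            raise TopologyError(f"{self.name}: no reference bead (ROH or linker)")
        if n_ref > 1:
            raise TopologyError(f"{self.name}: multiple sterol-hydroxyl beads")

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def reference_bead(self) -> int:
        """Index (within the molecule) of the ROH bead, else the first linker."""
        if "sterol-hydroxyl" in self.bead_roles:
            return self.bead_roles.index("sterol-hydroxyl")
        return self.bead_roles.index("linker")

    @property
    def tails(self) -> tuple[tuple[int, int], ...]:
        """(linker_index, terminal_tail_index) per tail.

        Tail i runs from linker bead i to the i-th ``tail-end`` bead; sterols
        have a single pseudo-tail from the ROH bead to their last bead.
        """
        ends = [i for i, r in enumerate(self.bead_roles) if r == "tail-end"]
        if "sterol-hydroxyl" in self.bead_roles:
            start = self.bead_roles.index("sterol-hydroxyl")
            return tuple((start, e) for e in ends[:1])
        linkers = [i for i, r in enumerate(self.bead_roles) if r == "linker"]
        return tuple((linkers[min(i, len(linkers) - 1)], e) for i, e in enumerate(ends))


def _glycero(name: str, cls: str, charge: float, leaflet: int) -> LipidSpecies:
    return LipidSpecies(
        name=name, headgroup_class=cls, charge=charge, leaflet=leaflet,
        bead_names=("HEAD", "GL1", "GL2", "C1A", "C2A", "C3A", "C1B", "C2B", "C3B"),
        bead_roles=("headgroup", "linker", "linker",
                    "tail", "tail", "tail-end", "tail", "tail", "tail-end"),
    )


def _sphingo(name: str, cls: str, charge: float, leaflet: int,
             headed: bool = True, flip: bool = False) -> LipidSpecies:
    head: tuple = (("HEAD",), ("headgroup",)) if headed else ((), ())
    return LipidSpecies(
        name=name, headgroup_class=cls, charge=charge, leaflet=leaflet,
        bead_names=head[0] + ("AM1", "AM2", "C1A", "C2A", "C3A", "C1B", "C2B", "C3B"),
        bead_roles=head[1] + ("linker", "linker",
                              "tail", "tail", "tail-end", "tail", "tail", "tail-end"),
        flip_capable=flip,
    )


def default_species(leaflet: int, headgroup_class: str) -> LipidSpecies:
    """Canonical bead layout for each headgroup class."""
    cls = headgroup_class
    if cls == "CHOL":
        return LipidSpecies(
            name="CHOL", headgroup_class="CHOL", charge=0.0, leaflet=leaflet,
            bead_names=("ROH", "R1", "R2", "C2"),
            bead_roles=("sterol-hydroxyl", "tail", "tail", "tail-end"),
            flip_capable=True,
        )
    if cls in ("SM", "GM"):
        return _sphingo(cls, cls, -1.0 if cls == "GM" else 0.0, leaflet)
    if cls == "CER":
        return _sphingo("CER", "CER", 0.0, leaflet, headed=False, flip=True)
    if cls == "DAG":
        return LipidSpecies(
            name="DAG", headgroup_class="DAG", charge=0.0, leaflet=leaflet,
            bead_names=("GL1", "GL2", "C1A", "C2A", "C3A", "C1B", "C2B", "C3B"),
            bead_roles=("linker", "linker",
                        "tail", "tail", "tail-end", "tail", "tail", "tail-end"),
            flip_capable=True,
        )
    if cls == "LPC":
        return LipidSpecies(
            name="LPC", headgroup_class="LPC", charge=0.0, leaflet=leaflet,
            bead_names=("HEAD", "GL1", "C1A", "C2A", "C3A"),
            bead_roles=("headgroup", "linker", "tail", "tail", "tail-end"),
        )
    charges = {"PS": -1.0, "PI": -1.0, "PA": -1.0,
               "PIP1": -3.0, "PIP2": -5.0, "PIP3": -7.0}
    return _glycero(cls, cls, charges.get(cls, 0.0), leaflet)


@dataclass
class ProteinTopology:
    """One protomer: residue numbering, bead indices, helix assignments."""

    protein_id: int
    conformation: str  # "inactive" | "active"
    residue_numbers: np.ndarray  # 1-based labels, 65..352
    bb_index: np.ndarray  # global bead index of the BB bead, per residue
    sc_indices: list[np.ndarray] = field(default_factory=list)
    helix_map: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_HELIX_MAP))
    bw_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conformation not in ("inactive", "active"):
            raise TopologyError(f"conformation must be inactive/active, got {self.conformation!r}")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.bb_index = np.asarray(self.bb_index, dtype=int)
        if self.residue_numbers.shape != self.bb_index.shape:
            raise TopologyError("residue_numbers and bb_index must align")
        # helix ranges must be disjoint
        spans = sorted(self.helix_map.values())
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c <= b:
                raise TopologyError("helix residue ranges overlap")

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def helix_residue_mask(self, helix: str) -> np.ndarray:
        lo, hi = self.helix_map[helix]
        return (self.residue_numbers >= lo) & (self.residue_numbers <= hi)

    def helix_bb_indices(self, helix: str) -> np.ndarray:
        return self.bb_index[self.helix_residue_mask(helix)]

    def helix_sc_indices(self, helix: str) -> np.ndarray:
        mask = self.helix_residue_mask(helix)
        out = [self.sc_indices[i] for i in np.nonzero(mask)[0] if len(self.sc_indices)]
        return np.concatenate(out) if out else np.empty(0, dtype=int)


@dataclass
class SystemTopology:
    """Full system: lipid molecule table + protomer table + box."""

    species: list[LipidSpecies]
    lipid_species_index: np.ndarray  # (n_lipids,) index into species
    lipid_leaflet: np.ndarray        # (n_lipids,) +1 / -1, leaflet of origin
    lipid_first_bead: np.ndarray     # (n_lipids,) global index of first bead
    proteins: list[ProteinTopology]
    box: np.ndarray                  # (3,) nm

    def __post_init__(self) -> None:
        self.lipid_species_index = np.asarray(self.lipid_species_index, dtype=int)
        self.lipid_leaflet = np.asarray(self.lipid_leaflet, dtype=int)
        self.lipid_first_bead = np.asarray(self.lipid_first_bead, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TopologyError("box must be three positive lengths (nm)")

    # -- sizes ------------------------------------------------------------
    @property
    def n_lipids(self) -> int:
        return len(self.lipid_species_index)

    @property
    def n_protein_beads(self) -> int:
        n = 0
        for p in self.proteins:
            n += p.n_residues + sum(len(s) for s in p.sc_indices)
        return n

    @property
    def n_beads(self) -> int:
        n = self.n_protein_beads
        for si in self.lipid_species_index:
            n += self.species[si].n_beads
        return n

    # -- lipid helpers ----------------------------------------------------
    def lipid_species(self, i: int) -> LipidSpecies:
        return self.species[self.lipid_species_index[i]]

    def lipid_bead_slice(self, i: int) -> slice:
        start = self.lipid_first_bead[i]
        return slice(start, start + self.lipid_species(i).n_beads)

    def reference_bead_indices(self, lipid_ids: np.ndarray | None = None) -> np.ndarray:
        """Global bead index of every lipid's reference bead (ROH or GL1/AM1)."""
        ids = np.arange(self.n_lipids) if lipid_ids is None else np.asarray(lipid_ids)
        offs = np.array([self.species[self.lipid_species_index[i]].reference_bead
                         for i in ids], dtype=int)
        return self.lipid_first_bead[ids] + offs

    def lipids_of_class(self, headgroup_class: str) -> np.ndarray:
        keep = np.array([self.species[s].headgroup_class == headgroup_class
                         for s in self.lipid_species_index])
        return np.nonzero(keep)[0]

    def non_flipping_lipids(self) -> np.ndarray:
        """Lipids excluding the flip-capable species (CHOL, CER, DAG)."""
        keep = np.array([not self.species[s].flip_capable
                         for s in self.lipid_species_index])
        return np.nonzero(keep)[0]

    def all_protein_bb_indices(self) -> np.ndarray:
        if not self.proteins:
            return np.empty(0, dtype=int)
        return np.concatenate([p.bb_index for p in self.proteins])

    # -- sidecar serialization --------------------------------------------
    def to_json(self) -> str:
        obj = {
            "format": "protomem-topology",
            "version": 1,
            "box_nm": self.box.tolist(),
            "species": [
                {
                    "name": s.name, "headgroup_class": s.headgroup_class,
                    "charge": s.charge, "leaflet": s.leaflet,
                    "bead_names": list(s.bead_names),
                    "bead_roles": list(s.bead_roles),
                    "flip_capable": s.flip_capable,
                }
                for s in self.species
            ],
            "lipids": {
                "species_index": self.lipid_species_index.tolist(),
                "leaflet": self.lipid_leaflet.tolist(),
                "first_bead": self.lipid_first_bead.tolist(),
            },
            "proteins": [
                {
                    "protein_id": p.protein_id,
                    "conformation": p.conformation,
                    "residue_numbers": p.residue_numbers.tolist(),
                    "bb_index": p.bb_index.tolist(),
                    "sc_indices": [s.tolist() for s in p.sc_indices],
                    "helix_map": {k: list(v) for k, v in p.helix_map.items()},
                    "bw_labels": {str(k): v for k, v in p.bw_labels.items()},
                }
                for p in self.proteins
            ],
        }
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "SystemTopology":
        obj = json.loads(text)
        if obj.get("format") != "protomem-topology":
            raise TopologyError("not a protomem topology sidecar")
        species = [
            LipidSpecies(
                name=s["name"], headgroup_class=s["headgroup_class"],
                charge=s["charge"], leaflet=s["leaflet"],
                bead_names=tuple(s["bead_names"]), bead_roles=tuple(s["bead_roles"]),
                flip_capable=s["flip_capable"],
            )
            for s in obj["species"]
        ]
        proteins = [
            ProteinTopology(
                protein_id=p["protein_id"], conformation=p["conformation"],
                residue_numbers=np.array(p["residue_numbers"]),
                bb_index=np.array(p["bb_index"]),
                sc_indices=[np.array(s, dtype=int) for s in p["sc_indices"]],
                helix_map={k: tuple(v) for k, v in p["helix_map"].items()},
                bw_labels={int(k): v for k, v in p.get("bw_labels", {}).items()},
            )
            for p in obj["proteins"]
        ]
        return cls(
            species=species,
            lipid_species_index=np.array(obj["lipids"]["species_index"]),
            lipid_leaflet=np.array(obj["lipids"]["leaflet"]),
            lipid_first_bead=np.array(obj["lipids"]["first_bead"]),
            proteins=proteins,
            box=np.array(obj["box_nm"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SystemTopology":
        with open(path) as fh:
            return cls.from_json(fh.read())
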