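"""In-memory structure model.

A deliberately flat representation: a structure is a list of
:class:`AtomRecord` plus crystallographic metadata (unit cell, space
group, symmetry operators).  Chain/residue views are built on demand.
Coordinates are Cartesian angstroms; residue numbers follow author
numbering as deposited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: canonical three-letter -> one-letter codes for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class AtomRecord:
    """One atom (ATOM or HETATM) with author-numbered residue identity."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    icode: str = ""
    het: bool = False
    is_symmetry_copy: bool = False
    symmetry_op: int = 0  # index into StructureModel.symmetry_ops; 0 = identity

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)


@dataclass
class Residue:
    """Grouped view over the atoms of one (chain, number, icode) residue."""

    chain_id: str
    number: int
    name: str
    icode: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    @property
    def is_symmetry_copy(self) -> bool:
        return any(a.is_symmetry_copy for a in self.atoms)


@dataclass
class StructureModel:
    """Atoms plus crystal metadata.

    ``symmetry_ops`` holds fractional-space rigid transforms ``(R, t)``
    with ``R`` a 3x3 float array and ``t`` a fractional translation;
    index 0 is always the identity when the list is non-empty.
    """

    id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit_cell is not None:
            a, b, c = self.unit_cell[:3]
            if min(a, b, c) <= 0:
                raise ValueError("unit cell lengths must be positive")

    # -- views -------------------------------------------------------------

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        """Residues in file order, optionally restricted to one chain."""
        order: dict[tuple[str, int, str], Residue] = {}
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = a.residue_key()
            res = order.get(key)
            if res is None:
                res = Residue(a.chain_id, a.residue_number, a.residue_name, a.icode)
                order[key] = res
            res.atoms.append(a)
        return list(order.values())

    def polymer_residues(self, chain_id: str | None = None) -> list[Residue]:
        return [r for r in self.residues(chain_id)
                if r.name in THREE_TO_ONE and r.atom("CA") is not None]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter or "X" for r in self.polymer_residues(chain_id))

    # -- crystal helpers ---------------------------------------------------

    @property
    def has_cell(self) -> bool:
        return self.unit_cell is not None and self.space_group is not None

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix for the stored cell."""
        if self.unit_cell is None:
            raise ValueError("model has no unit cell")
        a, b, c, al, be, ga = self.unit_cell
        al, be, ga = (math.radians(x) for x in (al, be, ga))
        cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
        sin_ga = math.sin(ga)
        v = math.sqrt(1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga)
        return np.array([
            [a, b * cos_ga, c * cos_be],
            [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0.0, 0.0, c * v / sin_ga],
        ])

    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix())

    def copy(self) -> "StructureModel":
        return StructureModel(
            id=self.id,
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            unit_cell=self.unit_cell,
            space_group=self.space_group,
            symmetry_ops=[(r.copy(), t.copy()) for r, t in self.symmetry_ops],
        )
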