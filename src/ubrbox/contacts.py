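"""Metal coordination spheres, hydrogen bonds, and pocket waters.

The UBR box is a three-zinc-finger domain; each zinc is typed by the
residue classes of its coordinating donors (e.g. ``C2H2`` = two
cysteine sulfurs + two histidine nitrogens).  Hydrogen bonds are
reported on a heavy-atom distance criterion only — the target
structures carry no hydrogens, so no angle term is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, StructureModel
from .structure_io import select_atoms

logger = logging.getLogger(__name__)

DONOR_ELEMENTS = {"N", "O", "S"}
METAL_ELEMENTS_DEFAULT = frozenset({"ZN"})


@dataclass
class MetalSite:
    metal: AtomRecord
    donors: list[tuple[AtomRecord, float]]  # sorted by distance

    @property
    def pattern(self) -> str:
        return coordination_pattern(self)

    def donor_residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for a, _ in self.donors:
            seen.setdefault((a.chain_id, a.residue_number, a.residue_name), None)
        return list(seen)


def find_metal_sites(model: StructureModel,
                     metals: frozenset[str] | set[str] = METAL_ELEMENTS_DEFAULT,
                     cutoff: float = 3.0) -> list[MetalSite]:
    """One :class:`MetalSite` per metal atom, donors = N/O/S atoms within
    ``cutoff`` angstroms sorted by distance (metal atoms excluded)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    metals_up = {m.upper() for m in metals}
    metal_atoms = select_atoms(model, lambda a: a.element.upper() in metals_up)
    donor_atoms = select_atoms(
        model, lambda a: a.element.upper() in DONOR_ELEMENTS)
    sites: list[MetalSite] = []
    if donor_atoms:
        tree = cKDTree(np.vstack([a.position for a in donor_atoms]))
    for m in metal_atoms:
        donors: list[tuple[AtomRecord, float]] = []
        if donor_atoms:
            for idx in tree.query_ball_point(m.position, cutoff):
                a = donor_atoms[idx]
                d = float(np.linalg.norm(a.position - m.position))
                donors.append((a, d))
        donors.sort(key=lambda t: (t[1], t[0].chain_id, t[0].residue_number, t[0].name))
        sites.append(MetalSite(m, donors))
    return sites


def coordination_pattern(site: MetalSite) -> str:
    """Canonical donor pattern string, counting unique coordinating
    residues by class: ``C`` = Cys, ``H`` = His, ``X`` = anything else.
    Classes with zero count are omitted; a donor-free site is reported
    as ``"C0H0"`` with a warning."""
    if not site.donors:
        logger.warning("metal %s/%s%d has no coordinating donors",
                       site.metal.chain_id, site.metal.residue_name,
                       site.metal.residue_number)
        return "C0H0"
    counts = {"C": 0, "H": 0, "X": 0}
    for _, _, resname in site.donor_residues():
        cls = {"CYS": "C", "HIS": "H"}.get(resname, "X")
        counts[cls] += 1
    return "".join(f"{cls}{counts[cls]}" for cls in "CHX" if counts[cls] > 0)


@dataclass
class HBond:
    donor: AtomRecord      # naming is conventional: donor/acceptor are not
    acceptor: AtomRecord   # distinguishable without hydrogens
    distance: float

    def row(self) -> dict:
        def tag(a: AtomRecord) -> str:
            return f"{a.chain_id}/{a.residue_name}{a.residue_number}/{a.name}"
        return {"a": tag(self.donor), "b": tag(self.acceptor),
                "distance": round(self.distance, 3)}


def find_hbonds(model: StructureModel, selection_a, selection_b,
                max_distance: float = 3.5) -> list[HBond]:
    """Putative hydrogen bonds between two atom selections.

    Heavy-atom N/O/S pairs within ``max_distance``, excluding pairs in
    the same residue and pairs closer than 1.8 angstroms (covalent).
    ``selection_a``/``selection_b`` are atom predicates.
    """
    def polar(sel):
        return select_atoms(model, lambda a: sel(a) and a.element.upper() in DONOR_ELEMENTS)

    atoms_a, atoms_b = polar(selection_a), polar(selection_b)
    bonds: list[HBond] = []
    seen: set[tuple[int, int]] = set()
    for a in atoms_a:
        for b in atoms_b:
            if a is b or a.residue_key() == b.residue_key():
                continue
            key = (min(id(a), id(b)), max(id(a), id(b)))
            if key in seen:
                continue
            d = float(np.linalg.norm(a.position - b.position))
            if 1.8 <= d <= max_distance:
                seen.add(key)
                bonds.append(HBond(a, b, d))
    bonds.sort(key=lambda h: (h.distance, h.donor.chain_id, h.donor.residue_number))
    return bonds


def waters_near(model: StructureModel, anchor_selector,
                cutoff: float = 4.0) -> tuple[int, list[AtomRecord]]:
    """Unique water oxygens within ``cutoff`` of any atom matched by
    ``anchor_selector``; returns ``(count, water_atoms)``."""
    anchors = select_atoms(model, anchor_selector)
    waters = select_atoms(model, lambda a: a.is_water and a.element.upper() == "O")
    if not anchors or not waters:
        return 0, []
    tree = cKDTree(np.vstack([a.position for a in anchors]))
    hits = []
    for w in waters:
        d, _ = tree.query(w.position, k=1)
        if d <= cutoff:
            hits.append(w)
    return len(hits), hits
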