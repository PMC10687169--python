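"""Aromatic-ring geometry and pi-interaction classification.

A pi–pi contact between two aromatic rings is described by two numbers:
``r_cen``, the distance between the ring centroids, and ``gamma``, the
angle between the ring-plane normals folded into [0°, 90°].  Contacts
are binned into the three conventional stacking conformations —
parallel (small gamma), T-shaped (gamma near 90°) and an intermediate
band between them.  Cation–pi contacts are scored by the distance from
the cation centre (Lys NZ, or the centroid of the Arg guanidinium
NE/CZ/NH1/NH2 group) to the ring centroid, plus the angular offset of
that vector from the ring normal.

All geometry is heavy-atom only: the crystal structures this targets
(1.6–2.2 angstrom resolution) carry no reliable hydrogens.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .model import Residue, StructureModel

logger = logging.getLogger(__name__)

#: ring member atoms per residue type; TRP contributes two rings
RING_ATOMS: dict[str, list[tuple[str, list[str]]]] = {
    "PHE": [("six_membered", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("six_membered", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "HIS": [("five_membered", ["CG", "ND1", "CD2", "CE1", "NE2"])],
    "TRP": [
        ("five_membered", ["CG", "CD1", "CD2", "NE1", "CE2"]),
        ("six_membered", ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]),
    ],
}

#: cation groups tested for cation–pi contacts (residue -> atom names averaged)
CATION_GROUPS: dict[str, list[str]] = {
    "LYS": ["NZ"],
    "ARG": ["NE", "CZ", "NH1", "NH2"],
}


class DegeneratePlaneError(ValueError):
    """Raised when a plane fit is attempted on (near-)collinear points."""


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through ``points`` (n >= 3).

    Returns ``(centroid, unit_normal, planarity_rms)`` where the normal
    is the smallest principal axis of the centred coordinates and
    ``planarity_rms`` is the RMS out-of-plane deviation.  The normal
    sign follows a right-handed convention with respect to the first
    two points (irrelevant downstream: gamma is folded acute).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise DegeneratePlaneError("points are collinear or coincident")
    normal = vt[2]
    hand = np.cross(centered[0], centered[1])
    if np.dot(normal, hand) < 0:
        normal = -normal
    rms = float(s[2] / math.sqrt(pts.shape[0]))
    return centroid, normal / np.linalg.norm(normal), rms


@dataclass
class AromaticRing:
    residue: Residue
    ring_label: str  # six_membered | five_membered
    atom_names: list[str]
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float

    @property
    def tag(self) -> str:
        sym = "*" if self.residue.is_symmetry_copy else ""
        return f"{self.residue.chain_id}/{self.residue.name}{self.residue.number}{sym}"


def ring_descriptor(residue: Residue) -> list[AromaticRing]:
    """Aromatic ring(s) of a PHE/TYR/HIS/TRP residue.

    Rings with missing member atoms are skipped with a logged warning
    (partial rings would bias the centroid).
    """
    rings: list[AromaticRing] = []
    for label, names in RING_ATOMS.get(residue.name, []):
        atoms = [residue.atom(n) for n in names]
        if any(a is None for a in atoms):
            missing = [n for n, a in zip(names, atoms) if a is None]
            logger.warning("skipping %s ring of %s/%s%d: missing atoms %s",
                           label, residue.chain_id, residue.name, residue.number, missing)
            continue
        pts = np.vstack([a.position for a in atoms])  # type: ignore[union-attr]
        centroid, normal, rms = fit_plane(pts)
        rings.append(AromaticRing(residue, label, list(names), centroid, normal, rms))
    return rings


def pair_geometry(ring_a: AromaticRing, ring_b: AromaticRing) -> tuple[float, float]:
    """``(r_cen, gamma)`` for a ring pair; gamma folded into [0, 90] degrees."""
    r_cen = float(np.linalg.norm(ring_a.centroid - ring_b.centroid))
    cosg = abs(float(np.dot(ring_a.normal, ring_b.normal)))
    gamma = math.degrees(math.acos(min(1.0, cosg)))
    return r_cen, gamma


@dataclass(frozen=True)
class PiPiThresholds:
    """Classification bands: gamma bands are left-closed,
    [0, parallel_max) parallel, [parallel_max, t_shaped_min) intermediate,
    [t_shaped_min, 90] T-shaped; r_cen must fall in [r_min, r_max]."""

    r_min: float = 3.0
    r_max: float = 7.0
    parallel_max: float = 30.0
    t_shaped_min: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_min < self.r_max):
            raise ValueError("need 0 < r_min < r_max")
        if not (0.0 < self.parallel_max <= self.t_shaped_min <= 90.0):
            raise ValueError("need 0 < parallel_max <= t_shaped_min <= 90")


def classify_pi_pi(r_cen: float, gamma: float,
                   thresholds: PiPiThresholds = PiPiThresholds()) -> str:
    """Stacking class for ``(r_cen, gamma)``: parallel / intermediate /
    t_shaped, or ``"none"`` when r_cen lies outside the detection window."""
    if not 0.0 <= gamma <= 90.0:
        raise ValueError("gamma must lie in [0, 90] degrees")
    if not thresholds.r_min <= r_cen <= thresholds.r_max:
        return "none"
    if gamma < thresholds.parallel_max:
        return "parallel"
    if gamma < thresholds.t_shaped_min:
        return "intermediate"
    return "t_shaped"


@dataclass
class PiPiContact:
    ring_a: AromaticRing
    ring_b: AromaticRing
    r_cen: float
    gamma: float
    conformation: str
    intermolecular: bool

    def row(self) -> dict:
        return {
            "ring_a": self.ring_a.tag, "ring_b": self.ring_b.tag,
            "r_cen": round(self.r_cen, 3), "gamma": round(self.gamma, 2),
            "conformation": self.conformation,
            "intermolecular": self.intermolecular,
            "symmetry_op": max(a.symmetry_op for a in
                               self.ring_a.residue.atoms + self.ring_b.residue.atoms),
        }


def structure_rings(model: StructureModel,
                    selection=None) -> list[AromaticRing]:
    """All aromatic rings of the model, optionally filtered by a residue
    predicate ``selection(residue) -> bool``."""
    rings: list[AromaticRing] = []
    for res in model.residues():
        if selection is not None and not selection(res):
            continue
        rings.extend(ring_descriptor(res))
    return rings


def find_pi_pi_contacts(model: StructureModel, selection=None,
                        thresholds: PiPiThresholds = PiPiThresholds()) -> list[PiPiContact]:
    """All classified pi–pi contacts among rings of the model.

    Same-residue pairs (the two TRP rings) are excluded; contacts are
    sorted by ascending r_cen; ``intermolecular`` is set when the rings
    come from different chains or a symmetry copy is involved.
    """
    rings = structure_rings(model, selection)
    contacts: list[PiPiContact] = []
    for ra, rb in itertools.combinations(rings, 2):
        if ra.residue.chain_id == rb.residue.chain_id and \
           ra.residue.number == rb.residue.number and ra.residue.icode == rb.residue.icode:
            continue
        r_cen, gamma = pair_geometry(ra, rb)
        conf = classify_pi_pi(r_cen, gamma, thresholds)
        if conf == "none":
            continue
        inter = (ra.residue.chain_id != rb.residue.chain_id
                 or ra.residue.is_symmetry_copy or rb.residue.is_symmetry_copy)
        contacts.append(PiPiContact(ra, rb, r_cen, gamma, conf, inter))
    contacts.sort(key=lambda c: (c.r_cen, c.ring_a.tag, c.ring_b.tag))
    return contacts


@dataclass(frozen=True)
class PiCationCriteria:
    max_distance: float = 6.0
    max_offset_angle: float = 60.0


@dataclass
class PiCationContact:
    ring: AromaticRing
    cation_residue: Residue
    cation_atoms: list[str]
    distance: float
    offset_angle: float

    def row(self) -> dict:
        return {
            "ring": self.ring.tag,
            "cation": f"{self.cation_residue.chain_id}/{self.cation_residue.name}"
                      f"{self.cation_residue.number}",
            "distance": round(self.distance, 3),
            "offset_angle": round(self.offset_angle, 2),
        }


def find_pi_cation_contacts(model: StructureModel, selection=None,
                            criteria: PiCationCriteria = PiCationCriteria()
                            ) -> list[PiCationContact]:
    """Cation–pi contacts between Lys/Arg cation centres and aromatic rings.

    ``distance`` is cation centre to ring centroid; ``offset_angle`` is
    the acute angle between the centroid->cation vector and the ring
    normal (0 = directly above the ring face).
    """
    rings = structure_rings(model, selection)
    contacts: list[PiCationContact] = []
    for res in model.residues():
        names = CATION_GROUPS.get(res.name)
        if names is None:
            continue
        atoms = [res.atom(n) for n in names]
        if any(a is None for a in atoms):
            continue
        center = np.mean([a.position for a in atoms], axis=0)  # type: ignore[union-attr]
        for ring in rings:
            if (ring.residue.chain_id, ring.residue.number, ring.residue.icode) == \
                    (res.chain_id, res.number, res.icode):
                continue
            vec = center - ring.centroid
            dist = float(np.linalg.norm(vec))
            if dist == 0.0 or dist > criteria.max_distance:
                continue
            cosang = abs(float(np.dot(vec / dist, ring.normal)))
            offset = math.degrees(math.acos(min(1.0, cosang)))
            if offset > criteria.max_offset_angle:
                continue
            contacts.append(PiCationContact(ring, res, list(names), dist, offset))
    contacts.sort(key=lambda c: (c.distance, c.ring.tag))
    return contacts
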