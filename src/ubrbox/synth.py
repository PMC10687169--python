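"""Seeded synthetic-data generators.

Every analysis stage in the package has a generator here that builds an
input with known ground truth: idealized aromatic ring pairs at a
prescribed (r_cen, gamma), tetrahedral zinc sites with a prescribed
donor pattern, single-site ITC titrations at prescribed (n, K_D, dH)
under a stated instrument protocol, and Boltzmann melt curves at a
prescribed Tm.  All randomness is confined to this module and driven by
an explicit seed; the analysis modules are deterministic.
"""

from __future__ import annotations

import math
import re
from importlib import resources

import numpy as np

from .model import AtomRecord, StructureModel
from .thermo import MeltCurve, TitrationProtocol, TitrationSeries, boltzmann, itc_heats

_HEX_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
_PENT_NAMES = ["CG", "ND1", "CE1", "NE2", "CD2"]
_CC_AROMATIC = 1.39  # benzene C-C bond, angstroms
_CN_IMIDAZOLE = 1.37


def _ring_template(ring_type: str) -> tuple[list[str], list[str], np.ndarray]:
    """(atom names, elements, coordinates) for an idealized flat ring
    centred at the origin in the z=0 plane."""
    if ring_type in {"PHE", "TYR"}:
        names, k, bond = _HEX_NAMES, 6, _CC_AROMATIC
    elif ring_type == "HIS":
        names, k, bond = _PENT_NAMES, 5, _CN_IMIDAZOLE
    else:
        raise ValueError(f"unsupported ring residue type: {ring_type!r}")
    radius = bond / (2.0 * math.sin(math.pi / k))
    ang = np.arange(k) * 2.0 * math.pi / k
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                              np.zeros(k)])
    elements = [n[0] for n in names]
    return names, elements, coords


def make_ring_pair(r_cen: float, gamma: float,
                   ring_type: str | tuple[str, str] = "PHE") -> StructureModel:
    """Two idealized aromatic rings with exact pair geometry.

    Ring A lies in the z=0 plane at the origin; ring B is the same
    template rotated by ``gamma`` degrees about the x axis and placed
    with its centroid at (0, 0, ``r_cen``), so the measured centroid
    distance and inter-normal angle equal the request to numerical
    precision.  Rings are emitted as single-residue chains A and B.
    """
    if r_cen <= 0:
        raise ValueError("r_cen must be positive")
    if not 0.0 <= gamma <= 90.0:
        raise ValueError("gamma must lie in [0, 90] degrees")
    type_a, type_b = (ring_type, ring_type) if isinstance(ring_type, str) else ring_type
    atoms: list[AtomRecord] = []
    g = math.radians(gamma)
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, math.cos(g), -math.sin(g)],
                      [0.0, math.sin(g), math.cos(g)]])
    for chain, rtype, transform, shift in (
            ("A", type_a, np.eye(3), np.zeros(3)),
            ("B", type_b, rot_x, np.array([0.0, 0.0, r_cen]))):
        names, elements, coords = _ring_template(rtype)
        for nm, el, xyz in zip(names, elements, (transform @ coords.T).T + shift):
            atoms.append(AtomRecord(name=nm, element=el, residue_name=rtype,
                                    residue_number=1, chain_id=chain, position=xyz))
    return StructureModel(id=f"ringpair_{r_cen:g}_{gamma:g}", atoms=atoms)


_TETRAHEDRAL = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)
_OCTAHEDRAL = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])

_DONOR_SPEC = {  # class -> (residue name, donor atom name, element, default Zn-donor distance)
    "C": ("CYS", "SG", "S", 2.3),
    "H": ("HIS", "NE2", "N", 2.1),
    "X": ("HOH", "O", "O", 2.1),
}


def make_zinc_site(pattern: str, bond_length: float | None = None) -> StructureModel:
    """A zinc ion with donors placed on ideal tetrahedral (or, above four
    donors, octahedral) directions.

    ``pattern`` is a coordination string such as ``"C2H2"``, ``"C4"`` or
    ``"C3X1"`` (C = Cys SG, H = His NE2, X = water O).  ``bond_length``
    overrides the per-class default metal-donor distances.
    """
    tokens = re.findall(r"([A-Z])(\d+)", pattern.upper())
    if not tokens or "".join(f"{c}{n}" for c, n in tokens) != pattern.upper():
        raise ValueError(f"unparseable coordination pattern: {pattern!r}")
    classes: list[str] = []
    for cls, count in tokens:
        if cls not in _DONOR_SPEC:
            raise ValueError(f"unsupported donor class {cls!r} in {pattern!r}")
        classes.extend(cls * int(count))
    if not 1 <= len(classes) <= 6:
        raise ValueError("pattern must request between 1 and 6 donors")
    dirs = _TETRAHEDRAL if len(classes) <= 4 else _OCTAHEDRAL
    atoms = [AtomRecord(name="ZN", element="Zn", residue_name="ZN",
                        residue_number=1, chain_id="A",
                        position=np.zeros(3), het=True)]
    for i, cls in enumerate(classes):
        resname, atom_name, element, default_d = _DONOR_SPEC[cls]
        d = bond_length if bond_length is not None else default_d
        atoms.append(AtomRecord(name=atom_name, element=element,
                                residue_name=resname, residue_number=2 + i,
                                chain_id="A", position=dirs[i] * d,
                                het=resname == "HOH"))
    return StructureModel(id=f"znsite_{pattern}", atoms=atoms)


def make_water_box(n_per_axis: int = 4, spacing: float = 3.0,
                   origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> StructureModel:
    """A cubic grid of water oxygens (census oracle fixture)."""
    atoms = []
    num = 1
    for i in range(n_per_axis):
        for j in range(n_per_axis):
            for k in range(n_per_axis):
                pos = np.asarray(origin) + spacing * np.array([i, j, k], float)
                atoms.append(AtomRecord(name="O", element="O", residue_name="HOH",
                                        residue_number=num, chain_id="W",
                                        position=pos, het=True))
                num += 1
    return StructureModel(id="waterbox", atoms=atoms)


def make_toy_protein(sequence: str, seed: int = 0, chain_id: str = "A",
                     start_number: int = 1) -> StructureModel:
    """A C-alpha-only chain with the given sequence on a seeded
    self-avoiding-ish random walk (3.8 angstrom steps)."""
    rng = np.random.default_rng(seed)
    pos = np.zeros(3)
    atoms = []
    prev_dir = None
    for i, aa in enumerate(sequence.upper()):
        from .model import THREE_TO_ONE
        three = {v: k for k, v in THREE_TO_ONE.items()}.get(aa, "ALA")
        atoms.append(AtomRecord(name="CA", element="C", residue_name=three,
                                residue_number=start_number + i, chain_id=chain_id,
                                position=pos.copy()))
        v = rng.normal(size=3)
        if prev_dir is not None:
            v += 0.8 * prev_dir  # persistence keeps the walk extended
        v /= np.linalg.norm(v)
        prev_dir = v
        pos = pos + 3.8 * v
    return StructureModel(id="toyprotein", atoms=atoms)


def simulate_itc(n: float, kd: float, dh: float, protocol: TitrationProtocol,
                 noise_sd: float = 0.0, noise_relative: float = 0.0,
                 seed: int | None = None, n_injections: int | None = None,
                 baseline: float = 0.0) -> TitrationSeries:
    """A titration series from the single-site model plus Gaussian noise.

    Per-injection noise s.d. is ``noise_sd + noise_relative * |q_i|``
    (microcal); ``noise_relative=0.02`` is 2% proportional heat noise.
    Identical seeds give identical output.
    """
    if noise_sd < 0 or noise_relative < 0:
        raise ValueError("noise parameters must be non-negative")
    series = TitrationSeries(
        cell_volume=protocol.cell_volume, cell_conc=protocol.cell_conc,
        syringe_conc=protocol.syringe_conc,
        injection_volumes=protocol.injection_volumes(n_injections),
        heats=np.zeros(len(protocol.injection_volumes(n_injections))))
    q = itc_heats(n, kd, dh, baseline, series)
    if noise_sd > 0 or noise_relative > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(size=len(q)) * (noise_sd + noise_relative * np.abs(q))
    series.heats = q
    return series


def simulate_melt(tm: float, lower: float = 1000.0, upper: float = 3000.0,
                  slope: float = 1.5, noise_sd: float = 0.0,
                  noise_relative: float = 0.0, seed: int | None = None,
                  t_min: float = 25.0, t_max: float = 95.0,
                  step: float = 0.2) -> MeltCurve:
    """A Boltzmann melt curve over [t_min, t_max] with Gaussian noise.

    Noise s.d. is ``noise_sd + noise_relative * (upper - lower)`` signal
    units at every point (``noise_relative=0.01`` = 1% of amplitude).
    """
    if noise_sd < 0 or noise_relative < 0:
        raise ValueError("noise parameters must be non-negative")
    t = np.arange(t_min, t_max + step / 2.0, step)
    s = boltzmann(t, tm, lower, upper, slope)
    sd = noise_sd + noise_relative * abs(upper - lower)
    if sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(size=len(s)) * sd
    return MeltCurve(temperatures=t, signal=s)


#: author-numbering offset and diagnostic Zn2 position of the packaged
#: synthetic UBR-box fixture (UBR4 row numbered 1660-1729; the Zn2-
#: coordinating cysteine sits at author position 1724 = ungapped 65)
UBR_FIXTURE_ANCHOR = ("UBR4", 65)


def load_ubr_fixture() -> dict[str, str]:
    """The packaged 7-sequence UBR-box fixture (synthetic stand-in).

    Constructed sequences emulating the zinc-coordination architecture
    of the seven human UBR-box domains — conserved Zn1 C2H2 columns in
    all, a histidine at the Zn2-diagnostic column in UBR1-UBR3 and a
    cysteine there in UBR4-UBR7 — without being the real database
    sequences (not redistributable offline).
    """
    text = resources.files("ubrbox").joinpath(
        "data/ubr_box_synthetic.fasta").read_text()
    seqs: dict[str, str] = {}
    sid = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith(">"):
            sid = line[1:].split()[0]
            seqs[sid] = ""
        elif sid:
            seqs[sid] += line
    return seqs
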