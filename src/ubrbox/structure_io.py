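"""Structure reading/writing, atom selection, and symmetry expansion.

gemmi does the format work (mmCIF and PDB dialects, unit cell, space
group); this module converts to the flat :class:`~ubrbox.model.StructureModel`
used by the geometry and contact analyses, applying a single-conformer
altloc policy, and generates crystallographic symmetry mates so that
lattice contacts (e.g. an N-terminal degron docking into the binding
site of a neighbouring molecule) become ordinary interchain contacts.
"""

from __future__ import annotations

import itertools
from dataclasses import replace
from pathlib import Path
from typing import Callable, Iterable

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, StructureModel

Selector = Callable[[AtomRecord], bool]


class StructureParseError(ValueError):
    """Raised when a structure file cannot be read."""


def _pick_altloc(group: list[AtomRecord]) -> AtomRecord:
    # highest occupancy wins; ties resolved by altloc letter ('A' first)
    best = sorted(group, key=lambda a: (-a.occupancy, a.altloc))[0]
    return replace(best, altloc="", position=best.position.copy())


def parse_structure(source: str | Path, fmt: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    source:
        Path to the file.  The format is inferred from the extension
        unless ``fmt`` (``"mmcif"`` or ``"pdb"``) is given.
    fmt:
        Optional explicit format name.

    All ATOM/HETATM records of the first model are kept, including
    waters and metals.  Alternate conformations are collapsed to the
    highest-occupancy conformer (ties broken towards altloc ``A``).
    """
    path = Path(source)
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"mmcif", "cif", "pdb"}:
            raise ValueError(f"unknown structure format: {fmt!r}")
        cof = gemmi.CoorFormat.Mmcif if fmt in {"mmcif", "cif"} else gemmi.CoorFormat.Pdb
    else:
        cof = gemmi.CoorFormat.Detect
    try:
        st = gemmi.read_structure(str(path), format=cof)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(1 for _ in st[0].all()) == 0:
        raise StructureParseError(f"{path}: no atoms found")

    cell = st.cell
    unit_cell = None
    space_group = None
    ops: list[tuple[np.ndarray, np.ndarray]] = []
    if cell.is_crystal():
        unit_cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        space_group = st.spacegroup_hm or "P 1"
        sg = gemmi.SpaceGroup(space_group)
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            ops.append((rot, tran))

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            by_name: dict[str, list[AtomRecord]] = {}
            for at in res:
                rec = AtomRecord(
                    name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    altloc=at.altloc if at.has_altloc() else "",
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    icode=res.seqid.icode.strip(),
                    het=res.het_flag == "H",
                )
                by_name.setdefault(at.name, []).append(rec)
            for name in by_name:
                atoms.append(_pick_altloc(by_name[name]))

    return StructureModel(
        id=st.name or path.stem,
        atoms=atoms,
        unit_cell=unit_cell,
        space_group=space_group,
        symmetry_ops=ops,
    )


def write_structure(model: StructureModel, path: str | Path, fmt: str | None = None) -> None:
    """Write a model as PDB or mmCIF (by extension, or explicit ``fmt``)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = model.id
    if model.unit_cell is not None:
        st.cell = gemmi.UnitCell(*model.unit_cell)
    if model.space_group is not None:
        st.spacegroup_hm = model.space_group
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
            md.add_chain(ch)
            ch = md[len(md) - 1]
            chains[a.chain_id] = ch
        res = None
        if len(ch) > 0:
            last = ch[len(ch) - 1]
            if last.seqid.num == a.residue_number and last.name == a.residue_name:
                res = last
        if res is None:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.icode or " ")
            res.het_flag = "H" if a.het else "A"
            ch.add_residue(res)
            res = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        res.add_atom(at)
    st.add_model(md)
    st.setup_entities()
    if fmt in {"mmcif", "cif"}:
        st.make_mmcif_document().write_file(str(path))
    elif fmt == "pdb":
        st.write_pdb(str(path))
    else:
        raise ValueError(f"unknown structure format: {fmt!r}")


def select_atoms(model: StructureModel, selector: Selector | None = None) -> list[AtomRecord]:
    """Atoms matching ``selector``, in deterministic (chain, residue, name) order."""
    atoms = model.atoms if selector is None else [a for a in model.atoms if selector(a)]
    return sorted(atoms, key=lambda a: (a.chain_id, a.residue_number, a.icode, a.name, a.element))


def _shift_range(frac_t: np.ndarray, frac_o: np.ndarray, margin: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """Integer lattice shifts for which the transformed fractional bounding
    box (inflated by ``margin`` per axis) can overlap the original box."""
    ranges = []
    for ax in range(3):
        lo = int(np.floor(frac_o[:, ax].min() - frac_t[:, ax].max() - margin[ax])) - 1
        hi = int(np.ceil(frac_o[:, ax].max() - frac_t[:, ax].min() + margin[ax])) + 1
        ranges.append(range(lo, hi + 1))
    return itertools.product(*ranges)


def expand_symmetry(model: StructureModel, radius: float = 5.0) -> StructureModel:
    """Append crystallographic symmetry mates within ``radius`` angstroms.

    Every space-group operator (and the lattice translations of each)
    is applied to the asymmetric unit; an image is kept whenever any of
    its atoms lies within ``radius`` of an original atom.  Copies carry
    ``is_symmetry_copy=True``, the generating operator index, and a
    chain label of the form ``A~<op>[+i+j+k]`` so reports stay
    reproducible.  Original atoms are returned unmodified.
    """
    if not model.has_cell:
        raise ValueError(
            "model has no unit cell/space group; run the contact search "
            "without symmetry expansion")
    if radius <= 0:
        raise ValueError("radius must be positive")
    out = model.copy()
    if not model.atoms:
        return out
    orth = model.orthogonalization_matrix()
    frac = model.fractionalization_matrix()
    xyz = model.coords()
    fr = (frac @ xyz.T).T
    tree = cKDTree(xyz)
    # per-axis fractional margin for a Cartesian radius (with safety pad)
    axis_len = np.linalg.norm(orth, axis=0)
    margin = radius / axis_len + 0.05

    ops = model.symmetry_ops or [(np.eye(3), np.zeros(3))]
    for op_idx, (rot, tran) in enumerate(ops):
        fr_t = (rot @ fr.T).T + tran
        for shift in _shift_range(fr_t, fr, margin):
            sh = np.asarray(shift, dtype=float)
            if op_idx == 0 and np.all(sh == 0):
                continue  # identity
            xyz_img = (orth @ (fr_t + sh).T).T
            d, _ = tree.query(xyz_img, k=1)
            if d.min() > radius:
                continue
            label_shift = "" if np.all(sh == 0) else "%+d%+d%+d" % tuple(shift)
            for a, pos in zip(model.atoms, xyz_img):
                out.atoms.append(replace(
                    a,
                    position=pos.copy(),
                    chain_id=f"{a.chain_id}~{op_idx}{label_shift}",
                    is_symmetry_copy=True,
                    symmetry_op=op_idx,
                ))
    return out
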