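"""Rigid-body least-squares superposition (Kabsch) and structure alignment.

``kabsch_superpose`` operates on paired coordinate sets;
``align_structures`` pairs C-alpha atoms of two models by global
sequence alignment first, with an optional iterative outlier trim for
comparing divergent domains (flexible loops otherwise dominate the
RMSD of a rigid fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import StructureModel
from .seqalign import GAP, needleman_wunsch


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper (det +1)
    translation: np.ndarray   # applied as x -> R @ x + t
    rmsd: float
    n_pairs: int
    pairing: list[tuple[str, str]] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (self.rotation @ np.asarray(coords, float).T).T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping ``coords_b`` onto
    ``coords_a`` in the least-squares sense (reflections excluded).

    Requires n >= 3 non-degenerate (non-collinear) points.
    """
    A = np.asarray(coords_a, float)
    B = np.asarray(coords_b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("rank-deficient (collinear) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A - ((R @ B.T).T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(R, t, rmsd, n)


def align_structures(model_a: StructureModel, model_b: StructureModel,
                     chain_a: str | None = None, chain_b: str | None = None,
                     trim: bool = False, trim_factor: float = 2.0,
                     max_cycles: int = 10) -> SuperpositionResult:
    """Superpose two models on sequence-aligned C-alpha pairs.

    Residues are paired by global alignment of the chain sequences
    (first chain of each model unless given); matched columns with both
    C-alphas present are superposed.  With ``trim`` enabled, pairs
    deviating more than ``trim_factor * rmsd`` are discarded and the
    fit repeated until stable (never below 3 pairs) — an outlier-
    rejecting protocol comparable to interactive "align" commands.
    """
    ca_id = chain_a or model_a.chain_ids()[0]
    cb_id = chain_b or model_b.chain_ids()[0]
    res_a = model_a.polymer_residues(ca_id)
    res_b = model_b.polymer_residues(cb_id)
    if len(res_a) < 3 or len(res_b) < 3:
        raise ValueError("need at least 3 alignable residues per model")
    seq_a = "".join(r.one_letter or "X" for r in res_a)
    seq_b = "".join(r.one_letter or "X" for r in res_b)
    row_a, row_b, _ = needleman_wunsch(seq_a, seq_b)

    pairs: list[tuple[np.ndarray, np.ndarray, str, str]] = []
    ia = ib = 0
    for ca_ch, cb_ch in zip(row_a, row_b):
        if ca_ch != GAP and cb_ch != GAP:
            ra, rb = res_a[ia], res_b[ib]
            aa, ab = ra.atom("CA"), rb.atom("CA")
            if aa is not None and ab is not None:
                pairs.append((aa.position, ab.position,
                              f"{ra.chain_id}/{ra.name}{ra.number}",
                              f"{rb.chain_id}/{rb.name}{rb.number}"))
        if ca_ch != GAP:
            ia += 1
        if cb_ch != GAP:
            ib += 1
    if len(pairs) < 3:
        raise ValueError("fewer than 3 alignable residue pairs")

    keep = list(range(len(pairs)))
    result = None
    for _ in range(max_cycles if trim else 1):
        A = np.vstack([pairs[i][0] for i in keep])
        B = np.vstack([pairs[i][1] for i in keep])
        result = kabsch_superpose(A, B)
        result.pairing = [(pairs[i][2], pairs[i][3]) for i in keep]
        if not trim:
            break
        dev = np.linalg.norm(A - result.transform(B), axis=1)
        cut = trim_factor * result.rmsd
        new_keep = [i for i, d in zip(keep, dev) if d <= cut]
        if len(new_keep) < 3 or len(new_keep) == len(keep):
            break
        keep = new_keep
    assert result is not None
    return result
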