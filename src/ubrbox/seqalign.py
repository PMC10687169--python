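"""Global sequence alignment, progressive MSA, and subfamily typing.

The aligner is a standard affine-gap Needleman–Wunsch/Gotoh with
BLOSUM62 scores (gap open 10, extend 0.5).  Multiple alignments are
built progressively along a UPGMA guide tree computed from pairwise
percent identity; profiles are aligned column-against-column with
sum-of-pairs scoring (gaps score 0 against anything).

Subfamily typing reads one alignment column: UBR-box domains whose
second zinc ion is coordinated by a histidine at the diagnostic
position form subfamily 1 (UBR1-like); those with a cysteine there
form subfamily 2 (UBR4-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP = "-"


def _score(a: str, b: str) -> float:
    if a == GAP or b == GAP:
        return 0.0
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return float(_BLOSUM62["X", "X"])


def _validate(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq or not seq.isalpha():
        raise ValueError(f"empty or non-alphabetic sequence: {seq!r}")
    return seq


def needleman_wunsch(seq_a: str, seq_b: str, gap_open: float = 10.0,
                     gap_extend: float = 0.5) -> tuple[str, str, float]:
    """Affine-gap global alignment; returns (aligned_a, aligned_b, score).

    Implemented as profile-profile alignment of single sequences so the
    progressive step reuses the identical dynamic program.
    """
    ra, rb, score = align_profiles([_validate(seq_a)], [_validate(seq_b)],
                                   gap_open, gap_extend)
    return ra[0], rb[0], score


def _col_score(prof_a: list[str], i: int, prof_b: list[str], j: int) -> float:
    # sum-of-pairs, averaged, so scores are comparable across profile sizes
    tot = 0.0
    for sa in prof_a:
        for sb in prof_b:
            tot += _score(sa[i], sb[j])
    return tot / (len(prof_a) * len(prof_b))


def align_profiles(prof_a: list[str], prof_b: list[str], gap_open: float = 10.0,
                   gap_extend: float = 0.5) -> tuple[list[str], list[str], float]:
    """Gotoh alignment of two gapped profiles (lists of equal-length rows)."""
    n, m = len(prof_a[0]), len(prof_b[0])
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)   # match/mismatch ending state
    X = np.full((n + 1, m + 1), neg)   # gap in profile B (A column vs gap)
    Y = np.full((n + 1, m + 1), neg)   # gap in profile A
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    # traceback pointers: 0=M,1=X,2=Y
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _col_score(prof_a, i - 1, prof_b, j - 1)
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(prev))
            M[i, j] = prev[k] + s
            ptr_m[i, j] = k
            cand_x = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            k = int(np.argmax(cand_x))
            X[i, j] = cand_x[k]
            ptr_x[i, j] = 0 if k == 0 else 1
            cand_y = (M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            k = int(np.argmax(cand_y))
            Y[i, j] = cand_y[k]
            ptr_y[i, j] = 0 if k == 0 else 2

    ends = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(ends))
    score = float(ends[state])
    i, j = n, m
    cols: list[tuple[int, int]] = []  # (-1 means gap) pairs of source columns
    while i > 0 or j > 0:
        if state == 0:
            cols.append((i - 1, j - 1))
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append((i - 1, -1))
            state = int(ptr_x[i, j])
            i -= 1
        else:
            cols.append((-1, j - 1))
            state = int(ptr_y[i, j])
            j -= 1
        if i == 0 and j > 0 and state == 0:
            state = 2
        elif j == 0 and i > 0 and state == 0:
            state = 1
    cols.reverse()
    out_a = ["".join(s[ci] if ci >= 0 else GAP for ci, _ in cols) for s in prof_a]
    out_b = ["".join(s[cj] if cj >= 0 else GAP for _, cj in cols) for s in prof_b]
    return out_a, out_b, score


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    pairs = [(a, b) for a, b in zip(aligned_a, aligned_b) if a != GAP and b != GAP]
    if not pairs:
        return 0.0
    return 100.0 * sum(a == b for a, b in pairs) / len(pairs)


@dataclass
class MultipleAlignment:
    """Rows of equal length, keyed by sequence id (insertion order kept)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column(self, col: int) -> str:
        """1-based column as a string over sequences."""
        return "".join(r[col - 1] for r in self.rows)

    def column_of_residue(self, seq_id: str, position: int) -> int:
        """1-based alignment column holding the ``position``-th (1-based)
        ungapped residue of sequence ``seq_id``."""
        row = self.row(seq_id)
        count = 0
        for col, ch in enumerate(row, start=1):
            if ch != GAP:
                count += 1
                if count == position:
                    return col
        raise ValueError(f"{seq_id} has fewer than {position} residues")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def progressive_align(sequences: dict[str, str], gap_open: float = 10.0,
                      gap_extend: float = 0.5) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    The guide tree is average-linkage clustering of pairwise
    (100 - percent identity) distances from all-vs-all pairwise
    alignments; deterministic for a given input set regardless of
    input order (ties broken by sequence id).
    """
    ids = sorted(sequences)
    seqs = {i: _validate(sequences[i]) for i in ids}
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    if len(ids) == 2:
        a, b, _ = needleman_wunsch(seqs[ids[0]], seqs[ids[1]], gap_open, gap_extend)
        rows = {ids[0]: a, ids[1]: b}
        order = list(sequences)
        return MultipleAlignment(order, [rows[i] for i in order])

    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b, _ = needleman_wunsch(seqs[ids[i]], seqs[ids[j]], gap_open, gap_extend)
            dist[i, j] = dist[j, i] = 100.0 - percent_identity(a, b)
    tree = linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)}
    for k, (ia, ib, _, _) in enumerate(tree):
        ids_a, prof_a = clusters.pop(int(ia))
        ids_b, prof_b = clusters.pop(int(ib))
        out_a, out_b, _ = align_profiles(prof_a, prof_b, gap_open, gap_extend)
        clusters[n + k] = (ids_a + ids_b, out_a + out_b)
    final_ids, final_rows = clusters.popitem()[1]
    by_id = dict(zip(final_ids, final_rows))
    order = [i for i in sequences if i in by_id]  # original input order
    return MultipleAlignment(order, [by_id[i] for i in order])


@dataclass
class SubfamilyCall:
    sequence_id: str
    zn2_column_residue: str
    subfamily: str  # "1" | "2" | "unclassified"


def classify_subfamily(alignment: MultipleAlignment, anchor_id: str,
                       anchor_position: int) -> list[SubfamilyCall]:
    """Type each sequence by the residue aligned with the reference
    Zn2-coordinating site (``anchor_position`` = 1-based ungapped
    position in ``anchor_id``): H -> subfamily 1, C -> subfamily 2,
    anything else (including a gap) -> unclassified."""
    if anchor_id not in alignment.ids:
        raise ValueError(f"anchor id {anchor_id!r} not in alignment")
    col = alignment.column_of_residue(anchor_id, anchor_position)
    calls = []
    for sid, row in zip(alignment.ids, alignment.rows):
        ch = row[col - 1]
        fam = {"H": "1", "C": "2"}.get(ch, "unclassified")
        calls.append(SubfamilyCall(sid, ch, fam))
    return calls
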