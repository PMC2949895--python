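"""Global pairwise alignment (Needleman–Wunsch with affine gaps, Gotoh
three-state recursion) and the percent-mismatch distance derived from it.

The DP kernel works on a precomputed position-score matrix, so the same
kernel aligns residue pairs here and profile pairs in
:mod:`paralign.progressive`.  A gap of length L costs ``gap_open +
L * gap_extend``; end gaps are penalized like internal gaps.  Traceback
tie-break is diagonal, then up (gap in the second sequence), then left —
fixed so results are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from numba import njit

from .io_formats import GAP, SubstitutionMatrix, load_weight_matrix

NEG_INF = -1e300


@dataclass(frozen=True)
class AlignParams:
    """Scoring model: substitution matrix plus affine gap penalties."""

    matrix: SubstitutionMatrix
    gap_open: float
    gap_extend: float

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError(
                f"need gap_open >= gap_extend >= 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )


def default_params(alphabet: str = "protein") -> AlignParams:
    """Clustal-family defaults: Gonnet 250 / 10 / 0.1 for protein,
    NUC.4.4 / 15 / 6.66 for DNA."""
    if alphabet == "protein":
        return AlignParams(load_weight_matrix("GONNET250"), 10.0, 0.1)
    if alphabet == "dna":
        return AlignParams(load_weight_matrix("NUC.4.4"), 15.0, 6.66)
    raise ValueError(f"unknown alphabet {alphabet!r}")


@dataclass(frozen=True)
class PairAlignment:
    """One aligned pair: equal-length gapped rows, raw DP score, and the
    fraction-mismatch distance over gap-free columns."""

    row_a: str
    row_b: str
    score: float
    m: int
    n: int
    distance: float

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows differ in length")


@njit(cache=True)
def _gotoh_moves(S, gap_open, gap_extend):  # pragma: no cover - numba
    """Affine-gap global DP over position scores S (m x n).

    Returns (score, moves) with moves[k] in {0: diag, 1: up/consume row,
    2: left/consume column}, in alignment order.
    """
    m, n = S.shape
    H = np.empty((m + 1, n + 1))
    X = np.empty((m + 1, n + 1))  # gap in columns (vertical run)
    Y = np.empty((m + 1, n + 1))  # gap in rows (horizontal run)
    # tbH: which state realized H (0 diag, 1 X, 2 Y); tbX/tbY: 1 = extend
    tbH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    X[0, 0] = NEG_INF
    Y[0, 0] = NEG_INF
    for i in range(1, m + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
        Y[i, 0] = NEG_INF
        H[i, 0] = X[i, 0]
        tbH[i, 0] = 1
        tbX[i, 0] = 1
    for j in range(1, n + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
        X[0, j] = NEG_INF
        H[0, j] = Y[0, j]
        tbH[0, j] = 2
        tbY[0, j] = 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            x_open = H[i - 1, j] - gap_open - gap_extend
            x_ext = X[i - 1, j] - gap_extend
            if x_open >= x_ext:
                X[i, j] = x_open
                tbX[i, j] = 0
            else:
                X[i, j] = x_ext
                tbX[i, j] = 1
            y_open = H[i, j - 1] - gap_open - gap_extend
            y_ext = Y[i, j - 1] - gap_extend
            if y_open >= y_ext:
                Y[i, j] = y_open
                tbY[i, j] = 0
            else:
                Y[i, j] = y_ext
                tbY[i, j] = 1
            # preference: diagonal, then up (X), then left (Y)
            best = diag
            state = 0
            if X[i, j] > best:
                best = X[i, j]
                state = 1
            if Y[i, j] > best:
                best = Y[i, j]
                state = 2
            H[i, j] = best
            tbH[i, j] = state
    moves = np.empty(m + n, dtype=np.int8)
    k = m + n
    i, j = m, n
    state = tbH[i, j]
    while i > 0 or j > 0:
        if state == 0:
            k -= 1
            moves[k] = 0
            i -= 1
            j -= 1
            state = tbH[i, j]
        elif state == 1:
            k -= 1
            moves[k] = 1
            ext = tbX[i, j]
            i -= 1
            state = 1 if ext == 1 else tbH[i, j]
        else:
            k -= 1
            moves[k] = 2
            ext = tbY[i, j]
            j -= 1
            state = 2 if ext == 1 else tbH[i, j]
    return H[m, n], moves[k:]


def align_score_matrix(S: np.ndarray, gap_open: float, gap_extend: float) -> Tuple[float, np.ndarray]:
    """Run the DP on an arbitrary position-score matrix; returns
    (score, moves) with the documented tie-break."""
    m, n = S.shape
    if m == 0 and n == 0:
        return 0.0, np.empty(0, dtype=np.int8)
    if m == 0:
        return -(gap_open + n * gap_extend), np.full(n, 2, dtype=np.int8)
    if n == 0:
        return -(gap_open + m * gap_extend), np.full(m, 1, dtype=np.int8)
    score, moves = _gotoh_moves(np.ascontiguousarray(S, dtype=np.float64),
                                float(gap_open), float(gap_extend))
    return float(score), moves


def _apply_moves(a: str, b: str, moves: np.ndarray) -> Tuple[str, str]:
    ra, rb = [], []
    i = j = 0
    for mv in moves:
        if mv == 0:
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif mv == 1:
            ra.append(a[i]); rb.append(GAP); i += 1
        else:
            ra.append(GAP); rb.append(b[j]); j += 1
    return "".join(ra), "".join(rb)


def identity_distance(row_a: str, row_b: str) -> float:
    """1 - identical/aligned over columns where neither row is gapped;
    1.0 when no gap-free column exists."""
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not pairs:
        return 1.0
    ident = sum(1 for x, y in pairs if x == y)
    return 1.0 - ident / len(pairs)


def nw_align(seq_a: str, seq_b: str, params: AlignParams) -> PairAlignment:
    """Optimal global alignment of two residue strings under ``params``."""
    mat = params.matrix
    ca = mat.encode(seq_a) if seq_a else np.empty(0, dtype=np.int64)
    cb = mat.encode(seq_b) if seq_b else np.empty(0, dtype=np.int64)
    S = mat.scores[np.ix_(ca, cb)] if len(ca) and len(cb) else np.zeros((len(ca), len(cb)))
    score, moves = align_score_matrix(S, params.gap_open, params.gap_extend)
    row_a, row_b = _apply_moves(seq_a, seq_b, moves)
    return PairAlignment(
        row_a=row_a, row_b=row_b, score=score, m=len(seq_a), n=len(seq_b),
        distance=identity_distance(row_a, row_b),
    )


def pairwise_distance(seq_a: str, seq_b: str, params: AlignParams) -> float:
    """Fraction-mismatch distance in [0, 1].  Inputs are ordered
    canonically before aligning so d(a, b) == d(b, a) exactly."""
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    return nw_align(seq_a, seq_b, params).distance


def score_gapped_pair(row_a: str, row_b: str, params: AlignParams) -> float:
    """Score an already-aligned pair of gapped rows under the same model the
    aligner optimizes: substitution scores on residue-residue columns,
    affine penalties on gap runs, gap-gap columns dropped."""
    cols = [(x, y) for x, y in zip(row_a, row_b) if not (x == GAP and y == GAP)]
    mat, go, ge = params.matrix, params.gap_open, params.gap_extend
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in cols:
        if x == GAP:
            total -= ge if in_gap_a else go + ge
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            total -= ge if in_gap_b else go + ge
            in_gap_b, in_gap_a = True, False
        else:
            total += mat.score(x, y)
            in_gap_a = in_gap_b = False
    return total
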