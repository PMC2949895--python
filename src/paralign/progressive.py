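"""Stage (3): weighted profile-profile progressive alignment along the
guide tree, sum-of-pairs scoring, and window realignment.

Each guide-tree merge is an affine-gap DP between two profiles, where the
score of matching column p against column q is
``sum_a sum_b f_p(a) f_q(b) s(a, b)`` with weighted residue frequencies
(gap mass excluded).  Gaps introduced by an earlier merge are never
removed ("once a gap, always a gap").  No position-specific gap-penalty
heuristics are applied: the gap model is the same plain affine one used
for pairwise alignment — the package's one deliberate simplification
relative to classic Clustal-family aligners, documented in the methods
note.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .diststore import store_create
from .guidetree import GuideTree, nj_tree, sequence_weights
from .io_formats import GAP, Clade, SequenceRecord, SequenceSet
from .pairwise import AlignParams, align_score_matrix, default_params
from .scheduler import SchedulerConfig, run_distance_phase


@dataclass
class Alignment:
    """Gapped rows keyed by id, in input order."""

    ids: List[str]
    rows: Dict[str, str]
    alphabet: str = "protein"

    def __post_init__(self):
        if set(self.ids) != set(self.rows):
            raise ValueError("ids and rows disagree")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def L(self) -> int:
        return len(next(iter(self.rows.values())))

    def as_dict(self) -> Dict[str, str]:
        return {rid: self.rows[rid] for rid in self.ids}

    def degapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "").replace(".", "")

    def __len__(self) -> int:
        return len(self.ids)


class Profile:
    """A block of aligned member rows plus per-column weighted residue
    frequencies, ready for profile-profile DP."""

    def __init__(self, ids: List[str], codes: np.ndarray, weights: np.ndarray, n_symbols: int):
        self.ids = ids
        self.codes = codes  # (n_members, L); gap encoded as n_symbols
        self.weights = np.asarray(weights, dtype=np.float64)
        self.n_symbols = n_symbols

    @property
    def L(self) -> int:
        return self.codes.shape[1]

    def frequencies(self) -> np.ndarray:
        """(L, n_symbols) weighted residue frequencies; gap columns carry
        no mass, so each row sums to <= 1."""
        L, K = self.L, self.n_symbols
        F = np.zeros((L, K))
        total = self.weights.sum()
        for row, w in zip(self.codes, self.weights):
            mask = row < K
            np.add.at(F, (np.nonzero(mask)[0], row[mask]), w)
        return F / total if total > 0 else F

    @classmethod
    def from_record(cls, rec: SequenceRecord, weight: float, params: AlignParams) -> "Profile":
        codes = params.matrix.encode(rec.residues)[None, :]
        return cls([rec.id], codes.astype(np.int16), np.array([weight]), len(params.matrix.residues))


def merge_profiles(p1: Profile, p2: Profile, params: AlignParams) -> Profile:
    """Affine-gap DP between two profiles; previously placed gaps persist."""
    K = p1.n_symbols
    S12 = p1.frequencies() @ params.matrix.scores @ p2.frequencies().T
    _, moves = align_score_matrix(S12, params.gap_open, params.gap_extend)
    Lnew = len(moves)
    sel1 = moves != 2  # columns consuming profile 1
    sel2 = moves != 1
    rows1 = np.full((len(p1.ids), Lnew), K, dtype=np.int16)
    rows1[:, sel1] = p1.codes
    rows2 = np.full((len(p2.ids), Lnew), K, dtype=np.int16)
    rows2[:, sel2] = p2.codes
    return Profile(p1.ids + p2.ids, np.vstack([rows1, rows2]),
                   np.concatenate([p1.weights, p2.weights]), K)


def progressive_align(
    seqset: SequenceSet,
    tree: GuideTree,
    weights: Optional[Mapping[str, float]] = None,
    params: Optional[AlignParams] = None,
) -> Alignment:
    """Align a sequence set following the guide tree's merge order."""
    params = params or default_params(seqset.alphabet)
    if set(tree.leaf_names()) != set(seqset.ids):
        raise ValueError("guide tree leaves do not match the sequence set ids")
    if weights is None:
        weights = sequence_weights(tree)

    def build(node: Clade) -> Profile:
        if node.is_leaf:
            return Profile.from_record(seqset[node.name], weights.get(node.name, 1.0), params)
        prof = build(node.children[0])
        for child in node.children[1:]:
            prof = merge_profiles(prof, build(child), params)
        return prof

    profile = build(tree.root)
    residues = params.matrix.residues
    lookup = np.array(list(residues) + [GAP])
    rows = {rid: "".join(lookup[row]) for rid, row in zip(profile.ids, profile.codes)}
    aln = Alignment(ids=list(seqset.ids), rows=rows, alphabet=seqset.alphabet)
    for rec in seqset:  # hard invariant: de-gapping recovers every input
        if aln.degapped(rec.id) != rec.residues:
            raise AssertionError(f"row {rec.id} does not de-gap to its input")
    return aln


# ---------------------------------------------------------------------------
# Sum-of-pairs scoring


def _pair_score(a: np.ndarray, b: np.ndarray, scores: np.ndarray, gap_code: int,
                go: float, ge: float) -> float:
    keep = ~((a == gap_code) & (b == gap_code))
    a, b = a[keep], b[keep]
    res = (a != gap_code) & (b != gap_code)
    total = float(scores[a[res], b[res]].sum())
    for g in (a == gap_code, b == gap_code):
        if g.any():
            opens = int(g[0]) + int((g[1:] & ~g[:-1]).sum())
            total -= opens * go + int(g.sum()) * ge
    return total


def sp_score(alignment: Alignment, params: AlignParams,
             weights: Optional[Mapping[str, float]] = None) -> float:
    """Sum over unordered row pairs of the affine-gap score of their gapped
    rows (gap-gap columns ignored); the weighted variant multiplies each
    pair term by w_i * w_j."""
    mat = params.matrix
    gap_code = len(mat.residues)
    coded = {}
    lut = {ch: k for k, ch in enumerate(mat.residues)}
    lut[GAP] = gap_code
    for rid in alignment.ids:
        coded[rid] = np.fromiter((lut[c] for c in alignment.rows[rid]),
                                 dtype=np.int64, count=alignment.L)
    total = 0.0
    ids = alignment.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            term = _pair_score(coded[ids[i]], coded[ids[j]], mat.scores, gap_code,
                               params.gap_open, params.gap_extend)
            if weights is not None:
                term *= weights[ids[i]] * weights[ids[j]]
            total += term
    return total


# ---------------------------------------------------------------------------
# Three-stage pipeline and window realignment


def three_stage_align(
    seqset: SequenceSet,
    params: Optional[AlignParams] = None,
    mode: str = "memory",
    workspace=None,
    config: Optional[SchedulerConfig] = None,
    executor=None,
    checkpoint_dir=None,
    progress=None,
) -> Tuple[Alignment, Optional[GuideTree]]:
    """Distance matrix -> guide tree -> progressive alignment.

    A single-sequence set short-circuits to a trivial alignment.
    """
    params = params or default_params(seqset.alphabet)
    if seqset.N == 1:
        rec = seqset[0]
        return Alignment([rec.id], {rec.id: rec.residues}, seqset.alphabet), None
    store = store_create(seqset.N, mode=mode, path=workspace)
    try:
        run_distance_phase(seqset, params, store, config=config, executor=executor,
                           progress=progress)
        tree = nj_tree(store, ids=seqset.ids, checkpoint_dir=checkpoint_dir)
    finally:
        store.close()
    weights = sequence_weights(tree)
    return progressive_align(seqset, tree, weights, params), tree


def realign_region(alignment: Alignment, col_start: int, col_end: int,
                   params: Optional[AlignParams] = None) -> Alignment:
    """Re-run the full three-stage pipeline on the de-gapped fragments of a
    column window [col_start, col_end) and splice the result back in.
    Columns outside the window are untouched; a row whose fragment is
    empty re-enters as all-gap."""
    L = alignment.L
    if not (0 <= col_start < col_end <= L):
        raise ValueError(f"invalid column window [{col_start}, {col_end}) for L={L}")
    params = params or default_params(alignment.alphabet)
    fragments = {rid: alignment.rows[rid][col_start:col_end].replace(GAP, "")
                 for rid in alignment.ids}
    live = [rid for rid in alignment.ids if fragments[rid]]
    if not live:
        new_rows = {rid: "" for rid in alignment.ids}
    elif len(live) == 1:
        w = len(fragments[live[0]])
        new_rows = {rid: fragments[rid] if rid == live[0] else GAP * w
                    for rid in alignment.ids}
    else:
        subset = SequenceSet([
            SequenceRecord(rid, fragments[rid], alphabet=alignment.alphabet)
            for rid in live
        ])
        sub_aln, _ = three_stage_align(subset, params=params, mode="memory")
        w = sub_aln.L
        new_rows = {rid: sub_aln.rows[rid] if rid in sub_aln.rows else GAP * w
                    for rid in alignment.ids}
    spliced = {
        rid: alignment.rows[rid][:col_start] + new_rows[rid] + alignment.rows[rid][col_end:]
        for rid in alignment.ids
    }
    return Alignment(ids=list(alignment.ids), rows=spliced, alphabet=alignment.alphabet)
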