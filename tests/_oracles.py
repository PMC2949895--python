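"""Independent oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, brute-force
search, hand recursion) and never calls the implementation paths it checks.
"""
from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Exhaustive global-alignment oracle


@lru_cache(maxsize=None)
def move_patterns(m: int, n: int) -> Tuple[Tuple[int, ...], ...]:
    """Every monotone alignment path for lengths (m, n): tuples of moves
    0=diag, 1=consume-a, 2=consume-b."""
    if m == 0 and n == 0:
        return ((),)
    out: List[Tuple[int, ...]] = []
    if m > 0 and n > 0:
        out.extend(p + (0,) for p in move_patterns(m - 1, n - 1))
    if m > 0:
        out.extend(p + (1,) for p in move_patterns(m - 1, n))
    if n > 0:
        out.extend(p + (2,) for p in move_patterns(m, n - 1))
    return tuple(out)


def affine_gap_penalty(pattern: Sequence[int], gap_open: float, gap_extend: float) -> float:
    """Total gap cost of a move pattern: each maximal run of 1s or 2s is one
    gap costing open + len * extend."""
    total = 0.0
    prev = 0
    for mv in pattern:
        if mv != 0:
            if mv != prev:
                total += gap_open + gap_extend
            else:
                total += gap_extend
        prev = mv
    return total


def brute_force_best_scores(m: int, n: int, scores4: np.ndarray,
                            gap_open: float, gap_extend: float) -> np.ndarray:
    """Optimal global affine-gap score for *every* pair of sequences of
    lengths (m, n) over a k-letter alphabet, by enumerating all alignment
    patterns.  Returns a (k^m, k^n) array; sequence index = base-k digits."""
    k = scores4.shape[0]
    A = np.array(list(itertools.product(range(k), repeat=m)), dtype=np.int64).reshape(k**m, m)
    B = np.array(list(itertools.product(range(k), repeat=n)), dtype=np.int64).reshape(k**n, n)
    best = np.full((k**m, k**n), -np.inf)
    for pattern in move_patterns(m, n):
        gap_cost = affine_gap_penalty(pattern, gap_open, gap_extend)
        sub = np.zeros((k**m, k**n))
        i = j = 0
        for mv in pattern:
            if mv == 0:
                sub = sub + scores4[A[:, i][:, None], B[None, :, j]]
                i += 1
                j += 1
            elif mv == 1:
                i += 1
            else:
                j += 1
        np.maximum(best, sub - gap_cost, out=best)
    return best


def enumerate_sequences(alphabet: str, length: int) -> List[str]:
    return ["".join(t) for t in itertools.product(alphabet, repeat=length)]


# ---------------------------------------------------------------------------
# Scheduling

def optimal_makespan(costs: Sequence[float], m: int) -> float:
    """Brute-force optimal non-preemptive makespan over all worker
    assignments (m^len(costs) candidates)."""
    best = float("inf")
    for assign in itertools.product(range(m), repeat=len(costs)):
        loads = [0.0] * m
        for c, w in zip(costs, assign):
            loads[w] += c
        best = min(best, max(loads))
    return best


# ---------------------------------------------------------------------------
# Trees


def random_binary_tree(n_leaves: int, rng: np.random.Generator,
                       blen_range=(0.05, 1.0)):
    """Random rooted binary tree over labelled leaves with uniform branch
    lengths; returned as the package's Clade nodes (construction only —
    no inference code involved)."""
    from paralign.io_formats import Clade

    nodes = [Clade(name=f"L{k}") for k in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.uniform(*blen_range))
        right.length = float(rng.uniform(*blen_range))
        nodes.append(Clade(children=[left, right]))
    return nodes[0]


def tree_path_distances(root) -> Dict[Tuple[str, str], float]:
    """Leaf-to-leaf path lengths via straightforward recursion."""
    dists: Dict[Tuple[str, str], float] = {}

    def collect(node) -> Dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        sides = []
        for ch in node.children:
            depths = collect(ch)
            sides.append({name: d + float(ch.length or 0.0) for name, d in depths.items()})
        merged: Dict[str, float] = {}
        for a in range(len(sides)):
            for b in range(a + 1, len(sides)):
                for na, da in sides[a].items():
                    for nb, db in sides[b].items():
                        key = tuple(sorted((na, nb)))
                        dists[key] = da + db
            merged.update(sides[a])
        merged.update(sides[-1])
        return merged

    collect(root)
    return dists


def distance_matrix_from_tree(root, ids: Sequence[str]) -> np.ndarray:
    dists = tree_path_distances(root)
    N = len(ids)
    D = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            D[i, j] = D[j, i] = dists[tuple(sorted((ids[i], ids[j])))]
    return D


def unrooted_splits(root) -> FrozenSet[FrozenSet[str]]:
    """Non-trivial bipartitions of the leaf set induced by internal edges,
    for topology comparison independent of root placement."""
    all_leaves = frozenset(root.leaf_names())
    splits = set()

    def walk(node):
        for ch in node.children:
            below = frozenset(ch.leaf_names())
            if 1 < len(below) < len(all_leaves) - 1:
                splits.add(frozenset({below, all_leaves - below}))
            walk(ch)

    walk(root)
    return frozenset(splits)
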