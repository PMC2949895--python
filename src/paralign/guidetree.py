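"""Stage (2): neighbor-joining guide tree from the distance store.

Saitou-Nei NJ with the standard Q-criterion; deterministic tie-break
(lowest index pair); negative branch lengths are clamped to zero with the
deficit moved to the sibling branch; the final unrooted tree is rooted at
the midpoint of the longest leaf-to-leaf path.  Each agglomerative join
can be checkpointed as a stage-numbered Newick snapshot.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .diststore import DistanceStore
from .io_formats import Clade, write_newick

_WEIGHT_FLOOR = 1e-9


@dataclass
class GuideTree:
    """Rooted binary tree with branch lengths; drives progressive
    alignment order and sequence weighting."""

    root: Clade
    join_order: List[Tuple[Tuple[str, ...], Tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def leaf_names(self) -> List[str]:
        return self.root.leaf_names()

    def validate(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise AssertionError("duplicate leaf labels")
        def rec(node: Clade) -> int:
            if node.is_leaf:
                return 1
            if len(node.children) != 2:
                raise AssertionError("guide tree must be binary")
            counts = [rec(ch) for ch in node.children]
            for ch in node.children:
                if ch.length is None or ch.length < 0:
                    raise AssertionError("missing or negative branch length")
            return sum(counts)
        if rec(self.root) != len(names):
            raise AssertionError("leaf count mismatch")


def checkpoint_tree(tree_state, directory, stage: int, stem: str = "tree-") -> Path:
    """Write one stage-numbered Newick snapshot (same 9-digit suffix
    convention as the pair spool)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stem}{stage:09d}.nwk"
    write_newick(tree_state, path)
    return path


def _nj_join_lengths(d_ij: float, r_i: float, r_j: float, r: int) -> Tuple[float, float]:
    if r > 2:
        li = 0.5 * d_ij + (r_i - r_j) / (2.0 * (r - 2))
    else:
        li = 0.5 * d_ij
    lj = d_ij - li
    # clamp negatives to zero, moving the deficit onto the sibling branch
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(store: DistanceStore, ids: Optional[Sequence[str]] = None,
            checkpoint_dir=None) -> GuideTree:
    """Neighbor joining over a complete distance store.

    ``ids`` labels the leaves (defaults to ``seq0..seqN-1``).  With
    ``checkpoint_dir`` set, every join writes a Newick snapshot of the
    current cluster forest (joined clusters under a provisional root);
    the last snapshot is the returned rooted tree.
    """
    N = store.N
    if ids is None:
        ids = [f"seq{k}" for k in range(N)]
    if len(ids) != N:
        raise ValueError(f"{len(ids)} ids for N={N} sequences")
    D = store.to_array()  # raises on incomplete store
    nodes: List[Clade] = [Clade(name=str(rid)) for rid in ids]
    active = list(range(N))
    join_order: List[Tuple[Tuple[str, ...], Tuple[str, ...]]] = []
    stage = 0

    def snapshot(tree_state):
        nonlocal stage
        if checkpoint_dir is not None:
            checkpoint_tree(tree_state, checkpoint_dir, stage)
        stage += 1

    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: lowest (a, b) in current index order
        flat = np.argmin(Q)
        a, b = divmod(int(flat), r)
        if a > b:
            a, b = b, a
        li, lj = _nj_join_lengths(sub[a, b], rowsum[a], rowsum[b], r)
        ia, ib = active[a], active[b]
        nodes[ia].length = li
        nodes[ib].length = lj
        parent = Clade(children=[nodes[ia], nodes[ib]])
        join_order.append((tuple(nodes[ia].leaf_names()), tuple(nodes[ib].leaf_names())))
        # distances from the new cluster to every other active cluster
        new_row = 0.5 * (D[ia, active] + D[ib, active] - sub[a, b])
        D[ia, active] = new_row
        D[active, ia] = new_row
        D[ia, ia] = 0.0
        nodes[ia] = parent
        active.pop(b)
        snapshot(Clade(children=[nodes[k] for k in active]))
    # final join of the last two clusters, half the remaining distance each
    ia, ib = active
    d = max(D[ia, ib], 0.0)
    nodes[ia].length = d / 2.0
    nodes[ib].length = d / 2.0
    join_order.append((tuple(nodes[ia].leaf_names()), tuple(nodes[ib].leaf_names())))
    root = Clade(children=[nodes[ia], nodes[ib]])
    root = _midpoint_root(root)
    tree = GuideTree(root=root, join_order=join_order)
    snapshot(tree.root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting


def _adjacency(root: Clade) -> Tuple[Dict[int, List[Tuple[int, float]]], Dict[int, Clade]]:
    """Unrooted adjacency over the tree's nodes, suppressing the degree-2
    root by fusing its two incident edges."""
    adj: Dict[int, List[Tuple[int, float]]] = {}
    by_id: Dict[int, Clade] = {}

    def add_edge(u: Clade, v: Clade, w: float):
        adj.setdefault(id(u), []).append((id(v), w))
        adj.setdefault(id(v), []).append((id(u), w))
        by_id[id(u)] = u
        by_id[id(v)] = v

    def walk(node: Clade):
        for ch in node.children:
            add_edge(node, ch, float(ch.length or 0.0))
            walk(ch)

    walk(root)
    if len(root.children) == 2:
        c1, c2 = root.children
        w = float((c1.length or 0.0) + (c2.length or 0.0))
        adj[id(c1)] = [(v, d) for v, d in adj[id(c1)] if v != id(root)] + [(id(c2), w)]
        adj[id(c2)] = [(v, d) for v, d in adj[id(c2)] if v != id(root)] + [(id(c1), w)]
        del adj[id(root)]
        del by_id[id(root)]
    return adj, by_id


def _midpoint_root(root: Clade) -> Clade:
    leaves = root.leaves()
    if len(leaves) <= 2:
        return root
    adj, by_id = _adjacency(root)

    def paths_from(src: int):
        dist = {src: 0.0}
        prev: Dict[int, int] = {}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    leaf_ids = {id(lf): lf for lf in leaves}
    best = None  # (-distance, nameA, nameB, srcid, dstid)
    prev_maps = {}
    for lid, leaf in sorted(leaf_ids.items(), key=lambda kv: kv[1].name):
        dist, prev = paths_from(lid)
        prev_maps[lid] = prev
        for other_id, other in leaf_ids.items():
            if other.name <= leaf.name:
                continue
            key = (-dist[other_id], leaf.name, other.name)
            if best is None or key < best[0]:
                best = (key, lid, other_id)
    (neg_d, _, _), src, dst = best
    total = -neg_d
    # reconstruct the path src -> dst
    prev = prev_maps[src]
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    path.reverse()
    # walk from src until the midpoint is crossed
    half = total / 2.0
    acc = 0.0
    for u, v in zip(path, path[1:]):
        w = next(d for x, d in adj[u] if x == v)
        if acc + w >= half or (u, v) == (path[-2], path[-1]):
            x = min(max(half - acc, 0.0), w)  # distance from u along (u, v)
            return _reroot_on_edge(adj, by_id, u, v, x, w)
        acc += w
    raise AssertionError("midpoint not located")  # pragma: no cover


def _reroot_on_edge(adj, by_id, u: int, v: int, x: float, w: float) -> Clade:
    """New root on edge (u, v) at distance x from u."""

    def build(node_id: int, parent_id: int, length: float) -> Clade:
        old = by_id[node_id]
        fresh = Clade(name=old.name if old.is_leaf else None, length=length)
        for nb, ew in adj[node_id]:
            if nb != parent_id:
                fresh.children.append(build(nb, node_id, ew))
        return fresh

    return Clade(children=[build(u, v, x), build(v, u, w - x)])


# ---------------------------------------------------------------------------
# Sequence weights


def sequence_weights(tree: GuideTree) -> Dict[str, float]:
    """Branch-sharing weights: each leaf accumulates, over the branches on
    its root path, branch length divided by the number of leaves below
    that branch; normalized so the maximum weight is 1.  A tree with zero
    total branch length yields uniform weights."""
    weights: Dict[str, float] = {}

    def rec(node: Clade, acc: float):
        if node.is_leaf:
            weights[node.name] = acc
            return
        for ch in node.children:
            share = float(ch.length or 0.0) / len(ch.leaves())
            rec(ch, acc + share)

    rec(tree.root, 0.0)
    if max(weights.values(), default=0.0) <= 0.0:
        return {name: 1.0 for name in weights}
    floored = {name: max(w, _WEIGHT_FLOOR) for name, w in weights.items()}
    top = max(floored.values())
    return {name: w / top for name, w in floored.items()}
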