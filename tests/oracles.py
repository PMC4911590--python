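"""Independent oracles used by the test suite and the acceptance script.

These deliberately share no algorithmic code with the package: tree
topologies are enumerated exhaustively and fitted by unconstrained least
squares, patristic distances are recomputed by walking the tree, and the
isoelectric point is found by a brute-force pH grid scan.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Unrooted binary tree space
# ---------------------------------------------------------------------------
# A topology is a frozenset of edges; an edge is a frozenset of two node
# labels.  Leaves are the given ids, internal nodes are integers.


def enumerate_topologies(ids: Sequence[str]) -> list[frozenset[frozenset]]:
    """All unrooted binary topologies on the given leaves (1, 3, 15, 105,
    945 ... for 3, 4, 5, 6, 7 leaves), built by inserting each leaf on every
    edge of every smaller topology."""
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need >= 3 leaves")
    star = frozenset(frozenset((leaf, 0)) for leaf in ids[:3])
    topologies = [star]
    next_internal = 1
    for leaf in ids[3:]:
        grown = []
        for topo in topologies:
            for edge in topo:
                u, v = tuple(edge)
                w = next_internal
                grown.append(
                    (topo - {edge})
                    | {frozenset((u, w)), frozenset((w, v)), frozenset((w, leaf))}
                )
        topologies = grown
        next_internal += 1
    return topologies


def _adjacency(topology: Iterable[frozenset]) -> dict:
    adj: dict = {}
    for edge in topology:
        u, v = tuple(edge)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _leaf_path_edges(topology, a, b) -> list[frozenset]:
    """Edges on the unique path between two leaves (DFS)."""
    adj = _adjacency(topology)
    stack = [(a, None, [])]
    while stack:
        node, parent, path = stack.pop()
        if node == b:
            return path
        for nxt in adj[node]:
            if nxt != parent:
                stack.append((nxt, node, path + [frozenset((node, nxt))]))
    raise RuntimeError("disconnected topology")


def ls_fit(topology, ids: Sequence[str], dmatrix: np.ndarray):
    """Least-squares branch lengths for a topology given leaf distances.

    Returns (rss, {edge: length}).
    """
    edges = sorted(topology, key=lambda e: tuple(sorted(map(str, e))))
    edge_index = {e: k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(ids)), 2))
    a_mat = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in _leaf_path_edges(topology, ids[i], ids[j]):
            a_mat[row, edge_index[e]] = 1.0
        y[row] = dmatrix[i, j]
    lengths, _, _, _ = np.linalg.lstsq(a_mat, y, rcond=None)
    rss = float(((a_mat @ lengths - y) ** 2).sum())
    return rss, dict(zip(edges, lengths))


def best_ls_topology(ids: Sequence[str], dmatrix: np.ndarray):
    """Exhaustive search: the topology with minimal least-squares residual.

    Returns (bipartition set, rss).
    """
    best = None
    for topo in enumerate_topologies(ids):
        rss, _ = ls_fit(topo, ids, dmatrix)
        if best is None or rss < best[1]:
            best = (topo, rss)
    return topology_bipartitions(best[0], ids), best[1]


def topology_bipartitions(topology, ids: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a topology, canonicalized to the side not
    containing the lexicographically smallest leaf."""
    leaves = set(ids)
    ref = min(leaves)
    adj = _adjacency(topology)
    parts = set()

    def leaves_beyond(node, banned) -> set:
        found = set()
        stack = [(node, banned)]
        while stack:
            cur, par = stack.pop()
            if cur in leaves:
                found.add(cur)
            for nxt in adj[cur]:
                if nxt != par:
                    stack.append((nxt, cur))
        return found

    for edge in topology:
        u, v = tuple(edge)
        side = leaves_beyond(u, v)
        if 2 <= len(side) <= len(leaves) - 2:
            parts.add(frozenset(leaves - side if ref in side else side))
    return parts


def random_additive_tree(ids: Sequence[str], rng: np.random.Generator):
    """A random topology with random branch lengths and its exact
    (additive) leaf distance matrix.

    Returns (bipartitions, distance matrix).
    """
    # build one random topology by random edge insertion
    ids = list(ids)
    topo = frozenset(frozenset((leaf, 0)) for leaf in ids[:3])
    next_internal = 1
    for leaf in ids[3:]:
        edges = sorted(topo, key=lambda e: tuple(sorted(map(str, e))))
        edge = edges[int(rng.integers(0, len(edges)))]
        u, v = tuple(edge)
        w = next_internal
        topo = (topo - {edge}) | {
            frozenset((u, w)), frozenset((w, v)), frozenset((w, leaf))
        }
        next_internal += 1
    lengths = {
        e: float(rng.uniform(0.1, 1.0))
        for e in sorted(topo, key=lambda e: tuple(sorted(map(str, e))))
    }
    n = len(ids)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[e] for e in _leaf_path_edges(topo, ids[i], ids[j]))
            dmat[i, j] = dmat[j, i] = d
    return topology_bipartitions(topo, ids), dmat


def tree_patristic(tree, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths of a cipkfam PhyloTree, recomputed by a
    direct root-path walk (independent of how the tree was built)."""
    node_paths: dict[str, list] = {}

    def walk2(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            node_paths[node.name] = acc
            return
        for child in node.children:
            walk2(child, acc)

    for child in tree.root.children:
        walk2(child, [])
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = node_paths[ids[i]], node_paths[ids[j]]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            d = sum(x.length for x in pa[k:]) + sum(x.length for x in pb[k:])
            out[i, j] = out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# Isoelectric point grid search
# ---------------------------------------------------------------------------

def grid_search_pi(
    sequence: str, pka: Mapping[str, float], resolution: float = 1e-5
) -> float:
    """Brute-force pI: the grid pH in [0, 14] with net charge closest to 0.

    Recomputes the Henderson–Hasselbalch charge directly from the pKa table.
    """
    seq = sequence.upper()
    grid = np.arange(0.0, 14.0 + resolution, resolution)
    charge = 1.0 / (1.0 + 10.0 ** (grid - pka["Nterm"]))
    charge = charge - 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - grid))
    for aa in ("H", "K", "R"):
        n = seq.count(aa)
        if n:
            charge = charge + n / (1.0 + 10.0 ** (grid - pka[aa]))
    for aa in ("C", "D", "E", "Y"):
        n = seq.count(aa)
        if n:
            charge = charge - n / (1.0 + 10.0 ** (pka[aa] - grid))
    return float(grid[np.abs(charge).argmin()])
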