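"""Distance-based protein phylogenetics: Poisson distances, neighbor-joining
and bootstrap supports.

The pipeline consumes an existing protein alignment (gapped FASTA), computes
pairwise distances under the Poisson correction with pairwise deletion of
gapped sites, builds an unrooted neighbor-joining (NJ) tree, and attaches
bootstrap supports by resampling alignment columns with replacement and
counting, for each internal edge of the original tree, the percentage of
replicate trees that contain the same bipartition.

The NJ implementation is the canonical Saitou–Nei agglomeration: at each
step join the pair (i, j) minimizing

    Q(i, j) = (n − 2) d(i, j) − Σ_k d(i, k) − Σ_k d(j, k)

with the standard two-point branch-length formulas.  Ties in Q are broken by
the lexicographically smallest id pair, which makes the output deterministic
and invariant to input order.  Negative branch lengths (possible on
non-additive data) are clamped to zero and the clamped deficit is recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "read_alignment_fasta",
    "p_distance_pairwise_deletion",
    "poisson_correct",
    "alignment_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "assign_subgroups",
    "write_distance_matrix",
]

GAP = "-"
DistanceModel = Literal["poisson", "p"]


@dataclass(frozen=True)
class Alignment:
    """A gapped protein alignment: parallel lists of ids and rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, column_indices: Sequence[int]) -> "Alignment":
        """A new alignment built from the given column indices (with
        repetition allowed) — the bootstrap resampling primitive."""
        cols = list(column_indices)
        return Alignment(
            self.ids,
            tuple("".join(row[c] for c in cols) for row in self.rows),
        )


def read_alignment_fasta(path: str | Path) -> Alignment:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])


def p_distance_pairwise_deletion(a_row: str, b_row: str) -> float:
    """Proportion of differing residues over sites where neither row is
    gapped.  Raises if no usable site remains."""
    if len(a_row) != len(b_row):
        raise ValueError("aligned rows differ in length")
    used = mismatches = 0
    for a, b in zip(a_row, b_row):
        if a == GAP or b == GAP:
            continue
        used += 1
        if a != b:
            mismatches += 1
    if used == 0:
        raise ValueError("no usable sites after pairwise deletion")
    return mismatches / used


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance d = −ln(1 − p) for a p-distance in [0, 1)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1): saturated or invalid")
    return -math.log1p(-p)


def alignment_distance_matrix(
    aln: Alignment, model: DistanceModel = "poisson"
) -> DistanceMatrix:
    """All pairwise distances of an alignment under the chosen model."""
    n = aln.n_taxa
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance_pairwise_deletion(aln.rows[i], aln.rows[j])
            d = poisson_correct(p) if model == "poisson" else p
            values[i, j] = values[j, i] = d
    return DistanceMatrix(aln.ids, values)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of a phylogenetic tree.

    Leaves carry a ``name``; internal nodes may carry a bootstrap
    ``support`` (percent).  ``length`` is the branch to the parent.
    """

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An unrooted tree stored rooted at its basal multifurcation."""

    def __init__(self, root: TreeNode, clamped_deficit: float = 0.0):
        self.root = root
        #: total branch length removed by clamping negative NJ estimates to 0
        self.clamped_deficit = clamped_deficit

    @property
    def leaf_names(self) -> list[str]:
        names: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                names.append(node.name or "")
            for child in node.children:
                walk(child)

        walk(self.root)
        return names

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (internal edges) of the unrooted tree.

        Each is canonicalized as the side that does not contain the
        lexicographically smallest leaf, so bipartition sets from trees over
        the same taxa are directly comparable.
        """
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = all_leaves - below if ref in below else below
                parts.add(side)
            return below

        walk(self.root)
        return parts

    def clade_sides(self) -> list[frozenset[str]]:
        """All leaf sets that form one side of some edge (including leaf
        edges) — the 'clades' of the unrooted tree.  Each edge contributes
        both of its sides."""
        all_leaves = frozenset(self.leaf_names)
        sides: list[frozenset[str]] = []

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                below = frozenset([node.name])
            else:
                below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                sides.append(below)
                sides.append(all_leaves - below)
            return below

        walk(self.root)
        return sides

    def newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path: str | Path, include_support: bool = True) -> None:
        Path(path).write_text(self.newick(include_support) + "\n")


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix (n >= 3 taxa).

    Deterministic: taxa are processed in lexicographic id order and Q-ties
    resolve to the smallest (i, j) pair in that order.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")

    order = sorted(range(n), key=lambda k: dm.ids[k])
    ids = [dm.ids[k] for k in order]
    d = dm.values[np.ix_(order, order)].copy()

    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    active = list(range(n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) position, i.e. lexicographically
        # earliest id pair given the sorted processing order
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        node = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)

        # distances from the new node u to every remaining k
        new_index = len(nodes)
        nodes.append(node)
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak, k in enumerate(active):
            if k in (i, j):
                continue
            d[new_index, k] = d[k, new_index] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new_index]

    # terminal trifurcation: three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].length = clamp(lk)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root, clamped_deficit=clamped)


def bootstrap_support(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: DistanceModel = "poisson",
    max_retries: int = 10,
    return_replicates: bool = False,
) -> PhyloTree | tuple[PhyloTree, list[list[int]]]:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times from a single
    RNG stream seeded with ``seed``; a replicate whose resampled alignment
    yields an undefined distance (no shared ungapped site, or a saturated
    p-distance of 1 under the Poisson model) is redrawn, at most
    ``max_retries`` times before erroring.  Each internal edge of the
    original tree receives the percentage of replicate trees containing the
    same bipartition.

    With ``return_replicates=True`` the resampled column index lists are
    returned as well, so supports can be recomputed independently.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(alignment_distance_matrix(aln, model))
    target = tree.bipartitions()
    counts: dict[frozenset[str], int] = {part: 0 for part in target}
    rng = np.random.default_rng(seed)
    n_cols = aln.n_columns
    replicates: list[list[int]] = []

    for _ in range(n_reps):
        for attempt in range(max_retries + 1):
            cols = rng.integers(0, n_cols, size=n_cols).tolist()
            try:
                rep_tree = nj_tree(
                    alignment_distance_matrix(aln.resample_columns(cols), model)
                )
            except ValueError:
                if attempt == max_retries:
                    raise ValueError(
                        "bootstrap replicate kept producing undefined "
                        f"distances after {max_retries} redraws"
                    )
                continue
            break
        replicates.append(cols)
        rep_parts = rep_tree.bipartitions()
        for part in counts:
            if part in rep_parts:
                counts[part] += 1

    supports = {part: 100.0 * c / n_reps for part, c in counts.items()}
    _attach_supports(tree, supports)
    if return_replicates:
        return tree, replicates
    return tree


def _attach_supports(tree: PhyloTree, supports: Mapping[frozenset[str], float]) -> None:
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root and 2 <= len(below) <= len(all_leaves) - 2:
            side = all_leaves - below if ref in below else below
            node.support = supports.get(side)
        return below

    walk(tree.root)


def assign_subgroups(
    tree: PhyloTree, anchors: Mapping[str, Iterable[str]]
) -> dict[str, str | None]:
    """Propagate subgroup labels from anchor leaves over the tree.

    ``anchors`` maps subgroup name → leaf ids known to belong to it (must be
    non-empty and disjoint).  An anchored leaf keeps its own label.  Every
    other leaf receives the subgroup of the smallest clade (side of an edge
    of the unrooted tree) that contains the leaf together with anchors of
    exactly one subgroup; if every such clade mixes subgroups the leaf is
    left unassigned (None).
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    anchor_of: dict[str, str] = {}
    for group, leaf_ids in anchors.items():
        for leaf in leaf_ids:
            if leaf in anchor_of:
                raise ValueError(f"leaf {leaf!r} anchored to multiple subgroups")
            anchor_of[leaf] = group
    leaves = tree.leaf_names
    missing = set(anchor_of) - set(leaves)
    if missing:
        raise ValueError(f"anchor leaves not in tree: {sorted(missing)}")

    # deterministic order: by size, then by content (set iteration order is
    # hash-dependent across interpreter runs)
    sides = sorted(set(tree.clade_sides()), key=lambda s: (len(s), tuple(sorted(s))))
    result: dict[str, str | None] = {}
    for leaf in leaves:
        if leaf in anchor_of:
            result[leaf] = anchor_of[leaf]
            continue
        assigned: str | None = None
        for side in sides:
            if leaf not in side:
                continue
            groups = {anchor_of[x] for x in side if x in anchor_of}
            if len(groups) == 1:
                assigned = groups.pop()
                break
            if len(groups) > 1:
                continue
        result[leaf] = assigned
    return result


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, name in enumerate(dm.ids):
            row = "\t".join(f"{dm.values[i, j]:.6f}" for j in range(len(dm.ids)))
            fh.write(f"{name}\t{row}\n")
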