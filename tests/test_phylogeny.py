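"""Distances, neighbor-joining, bootstrap supports and subgroup labels."""

import math

import numpy as np
import pytest

from cipkfam import phylogeny as ph
from cipkfam.phylogeny import (
    Alignment,
    DistanceMatrix,
    alignment_distance_matrix,
    assign_subgroups,
    bootstrap_support,
    nj_tree,
    p_distance_pairwise_deletion,
    poisson_correct,
)
from oracles import best_ls_topology, random_additive_tree, tree_patristic


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [("AAAA", "AAAA", 0.0), ("AAAA", "AAAT", 0.25), ("AA-A", "AAAT", 1 / 3)],
)
def test_p_distance_pairwise_deletion(a, b, expected):
    assert p_distance_pairwise_deletion(a, b) == pytest.approx(expected)


def test_p_distance_no_usable_sites():
    with pytest.raises(ValueError, match="no usable sites"):
        p_distance_pairwise_deletion("A--", "-AA")


def test_poisson_correction_values():
    assert poisson_correct(0.0) == 0.0
    assert poisson_correct(0.5) == pytest.approx(0.693147, abs=1e-6)
    with pytest.raises(ValueError):
        poisson_correct(1.0)


def test_poisson_correction_dominates_p():
    grid = np.linspace(0.0, 0.99, 50)
    corrected = [poisson_correct(p) for p in grid]
    assert all(d >= p for d, p in zip(corrected, grid))
    assert all(b > a for a, b in zip(corrected, corrected[1:]))  # monotone


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_three_point_formulas():
    ids = ("A", "B", "C")
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
    tree = nj_tree(DistanceMatrix(ids, d))
    # la = (ab+ac-bc)/2 = 0, lb = 2, lc = 3
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})


def test_nj_four_taxon_additive_example():
    ids = ("A", "B", "C", "D")
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(DistanceMatrix(ids, d))
    assert tree.bipartitions() == {frozenset({"C", "D"})}  # split AB|CD
    # the additive matrix is realized exactly: A:1 B:2 C:3 D:4 internal:1
    assert np.allclose(tree_patristic(tree, ids), d)
    oracle_split, rss = best_ls_topology(ids, d)
    assert oracle_split == tree.bipartitions()
    assert rss == pytest.approx(0.0, abs=1e-18)


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    _, d = random_additive_tree([f"t{i}" for i in range(8)], rng)
    ids = tuple(f"t{i}" for i in range(8))
    tree = nj_tree(DistanceMatrix(ids, d))
    perm = rng.permutation(8)
    tree_p = nj_tree(
        DistanceMatrix(tuple(ids[i] for i in perm), d[np.ix_(perm, perm)])
    )
    assert tree.bipartitions() == tree_p.bipartitions()
    assert tree.newick(include_support=False) == tree_p.newick(
        include_support=False
    )


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7])
def test_nj_matches_least_squares_oracle_on_additive_matrices(n_taxa):
    """Classical consistency: on additive data NJ recovers the unique
    minimal-RSS topology found by exhaustive least-squares search."""
    rng = np.random.default_rng(100 + n_taxa)
    ids = [f"t{i}" for i in range(n_taxa)]
    for _ in range(3):
        true_split, d = random_additive_tree(ids, rng)
        tree = nj_tree(DistanceMatrix(tuple(ids), d))
        assert tree.bipartitions() == true_split
        oracle_split, rss = best_ls_topology(ids, d)
        assert tree.bipartitions() == oracle_split
        assert rss < 1e-18
        assert np.allclose(tree_patristic(tree, ids), d, atol=1e-9)


@pytest.mark.parametrize("n_taxa", [9, 12])
def test_nj_recovers_random_additive_trees(n_taxa):
    rng = np.random.default_rng(200 + n_taxa)
    ids = [f"t{i}" for i in range(n_taxa)]
    for _ in range(3):
        true_split, d = random_additive_tree(ids, rng)
        tree = nj_tree(DistanceMatrix(tuple(ids), d))
        assert tree.bipartitions() == true_split
        assert np.allclose(tree_patristic(tree, ids), d, atol=1e-9)


def test_nj_agrees_with_scikit_bio():
    import skbio

    rng = np.random.default_rng(11)
    _, d = random_additive_tree([f"t{i}" for i in range(7)], rng)
    # perturb slightly so the matrix is non-additive but far from ties
    noise = rng.uniform(0, 0.01, size=d.shape)
    d = d + noise + noise.T
    d = 0.5 * (d + d.T)          # exact symmetry at float precision
    np.fill_diagonal(d, 0.0)
    ids = tuple(f"t{i}" for i in range(7))
    ours = nj_tree(DistanceMatrix(ids, d)).bipartitions()
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
    ref = min(ids)
    theirs = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(ids) - 2:
            theirs.add(frozenset(set(ids) - side) if ref in side else side)
    assert ours == theirs


def test_negative_branch_lengths_are_clamped():
    ids = ("A", "B", "C", "D")
    # strongly non-additive: forces a negative NJ length estimate
    d = np.array(
        [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1e-9], [4, 4, 1e-9, 0]], float
    )
    tree = nj_tree(DistanceMatrix(ids, d))

    def lengths(node):
        yield node.length
        for c in node.children:
            yield from lengths(c)

    assert all(l >= 0 for c in tree.root.children for l in lengths(c))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _four_taxon_alignment():
    # 10 split-informative columns + 10 constant columns
    rows = ["A" * 10 + "G" * 10, "A" * 10 + "G" * 10,
            "T" * 10 + "G" * 10, "T" * 10 + "G" * 10]
    return Alignment(("A", "B", "C", "D"), tuple(rows))


def test_bootstrap_unanimous_split_gets_full_support():
    tree = bootstrap_support(_four_taxon_alignment(), n_reps=100, seed=5)
    supports = [
        n.support for n in _internal_nodes(tree) if n.support is not None
    ]
    assert supports == [100.0]


def test_bootstrap_deterministic_under_fixed_seed():
    a = bootstrap_support(_four_taxon_alignment(), n_reps=50, seed=9)
    b = bootstrap_support(_four_taxon_alignment(), n_reps=50, seed=9)
    assert a.newick() == b.newick()


def test_bootstrap_supports_invariant_to_leaf_order():
    aln = _five_taxon_alignment()
    perm = Alignment(tuple(reversed(aln.ids)), tuple(reversed(aln.rows)))
    t1 = bootstrap_support(aln, n_reps=80, seed=3)
    t2 = bootstrap_support(perm, n_reps=80, seed=3)
    assert _support_map(t1) == _support_map(t2)


def _five_taxon_alignment():
    rng = np.random.default_rng(17)
    base = rng.choice(list("ACDEFGHIKL"), size=60)
    rows = []
    for group in (0, 0, 1, 1, 2):
        row = base.copy()
        mask = rng.random(60) < 0.25
        row[mask] = rng.choice(list("MNPQRSTVWY"), size=mask.sum())
        rows.append("".join(row))
    return Alignment(tuple("ABCDE"), tuple(rows))


def _internal_nodes(tree):
    out = []

    def walk(node):
        if not node.is_leaf:
            out.append(node)
            for c in node.children:
                walk(c)

    walk(tree.root)
    return out


def _support_map(tree):
    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    result = {}

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node.support is not None:
            side = all_leaves - below if ref in below else below
            result[side] = node.support
        return below

    walk(tree.root)
    return result


def test_bootstrap_replay_oracle_identity():
    """Supports must equal an exhaustive recount over the very same
    resampled column index lists."""
    aln = _five_taxon_alignment()
    tree, replicates = bootstrap_support(
        aln, n_reps=200, seed=21, return_replicates=True
    )
    assert len(replicates) == 200
    target = tree.bipartitions()
    counts = {part: 0 for part in target}
    for cols in replicates:
        rep_tree = nj_tree(
            alignment_distance_matrix(aln.resample_columns(cols))
        )
        parts = rep_tree.bipartitions()
        for part in counts:
            if part in parts:
                counts[part] += 1
    replayed = {part: 100.0 * c / 200 for part, c in counts.items()}
    assert _support_map(tree) == replayed


def test_bootstrap_supports_within_bounds():
    tree = bootstrap_support(_five_taxon_alignment(), n_reps=60, seed=2)
    for side, support in _support_map(tree).items():
        assert 0.0 <= support <= 100.0


# ---------------------------------------------------------------------------
# Subgroup assignment
# ---------------------------------------------------------------------------

def test_assign_subgroups_anchor_keeps_own_label():
    ids = ("A", "B", "C", "D")
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(DistanceMatrix(ids, d))
    labels = assign_subgroups(tree, {"I": ["A"], "II": ["C"]})
    assert labels["A"] == "I" and labels["C"] == "II"
    assert labels["B"] == "I" and labels["D"] == "II"


def test_assign_subgroups_requires_anchors():
    ids = ("A", "B", "C")
    d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], float)
    tree = nj_tree(DistanceMatrix(ids, d))
    with pytest.raises(ValueError):
        assign_subgroups(tree, {})
    with pytest.raises(ValueError):
        assign_subgroups(tree, {"I": ["A"], "II": ["A"]})


def test_assign_subgroups_planted_partition_recovery():
    """Four seed sequences mutated at low rate; one anchor per group must
    recover the planted group of every leaf."""
    rng = np.random.default_rng(99)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seeds = [rng.choice(alphabet, size=120) for _ in range(4)]
    ids, rows, truth = [], [], {}
    for g, seed_seq in enumerate(seeds):
        for k in range(4):
            row = seed_seq.copy()
            mask = rng.random(120) < 0.04
            row[mask] = rng.choice(alphabet, size=mask.sum())
            name = f"g{g}_m{k}"
            ids.append(name)
            rows.append("".join(row))
            truth[name] = f"G{g}"
    aln = Alignment(tuple(ids), tuple(rows))
    tree = nj_tree(alignment_distance_matrix(aln))
    anchors = {f"G{g}": [f"g{g}_m0"] for g in range(4)}
    labels = assign_subgroups(tree, anchors)
    assert labels == truth


def test_newick_is_readable_by_dendropy(tmp_path):
    import dendropy

    tree = bootstrap_support(_five_taxon_alignment(), n_reps=20, seed=1)
    path = tmp_path / "tree.nwk"
    tree.write_newick(path)
    loaded = dendropy.Tree.get(path=str(path), schema="newick")
    assert {t.taxon.label for t in loaded.leaf_node_iter()} == set("ABCDE")
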