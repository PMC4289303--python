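"""Distance-tree construction: NJ against a least-squares topology oracle,
bootstrap behaviour, rooting and group assignment."""

import itertools

import numpy as np
import pytest

from trlocus.phylogeny import (
    GroupConflictError,
    Node,
    PhyloTree,
    assign_phylo_groups,
    bootstrap_support,
    group_distribution,
    minimum_evolution,
    nj,
    ols_fit,
    root_with_outgroup,
    upgma,
)


# ---------------------------------------------------------------------------
# Oracle helpers
# ---------------------------------------------------------------------------

def enumerate_topologies(names):
    """All unrooted binary topologies via sequential edge insertion."""
    first = Node()
    for name in names[:3]:
        first.add(Node(name))
    trees = [PhyloTree(first)]
    for name in names[3:]:
        grown = []
        for tree in trees:
            edges = [n for n in tree.postorder() if n.parent is not None]
            for k in range(len(edges)):
                clone = PhyloTree.from_newick(
                    tree.newick(lengths=False, supports=False))
                edge = [n for n in clone.postorder() if n.parent is not None][k]
                parent = edge.parent
                mid = Node()
                parent.children[parent.children.index(edge)] = mid
                mid.parent = parent
                mid.add(edge)
                mid.add(Node(name))
                grown.append(clone)
        trees = grown
    return trees


def least_squares_best(names, d):
    """Brute force: OLS-fit every topology, return the minimum-SSE tree."""
    best, best_sse, best_lengths = None, None, None
    for tree in enumerate_topologies(names):
        sse, lengths = ols_fit(tree, names, d)
        if best_sse is None or sse < best_sse - 1e-12:
            best, best_sse, best_lengths = tree, sse, lengths
    return best, best_sse, best_lengths


def random_additive_tree(n, rng):
    nodes = Node()
    for i in range(3):
        nodes.add(Node(f"t{i}"))
    tree = PhyloTree(nodes)
    for i in range(3, n):
        edges = [x for x in tree.postorder() if x.parent is not None]
        edge = edges[rng.integers(len(edges))]
        parent = edge.parent
        mid = Node()
        parent.children[parent.children.index(edge)] = mid
        mid.parent = parent
        mid.add(edge)
        mid.add(Node(f"t{i}"))
    for x in tree.postorder():
        if x.parent is not None:
            x.length = x.raw_length = float(rng.uniform(0.05, 1.0))
    return tree


def path_matrix(tree, names):
    got_names, dm = tree.distance_matrix()
    idx = {nm: i for i, nm in enumerate(got_names)}
    perm = [idx[nm] for nm in names]
    return dm[np.ix_(perm, perm)]


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------

def test_two_taxa_edge_split_equally():
    tree = nj(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert lengths == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}


def test_three_equidistant_taxa_give_three_equal_branches():
    d = np.full((3, 3), 0.3)
    np.fill_diagonal(d, 0.0)
    tree = nj(["A", "B", "C"], d)
    assert len(tree.root.children) == 3
    assert all(c.length == pytest.approx(0.15) for c in tree.root.children)


def test_additive_four_taxon_matrix_recovered_exactly():
    # paths of the tree ((A:1,B:2):1,(C:3,D:1))
    names = list("ABCD")
    d = np.array([[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                 dtype=float)
    tree = nj(names, d)
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    assert np.allclose(path_matrix(tree, names), d)
    # least-squares oracle over all three quartet topologies agrees
    oracle, sse, _ = least_squares_best(names, d)
    assert sse == pytest.approx(0.0, abs=1e-18)
    assert oracle.bipartitions() == tree.bipartitions()


@pytest.mark.parametrize("n", [5, 6])
def test_nj_equals_least_squares_oracle_on_additive_matrices(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(3):
        true_tree = random_additive_tree(n, rng)
        names = sorted(true_tree.leaf_names())
        d = path_matrix(true_tree, names)
        built = nj(names, d)
        oracle, sse, _ = least_squares_best(names, d)
        assert sse == pytest.approx(0.0, abs=1e-16)
        assert built.bipartitions() == oracle.bipartitions()
        assert np.allclose(path_matrix(built, names), d)


@pytest.mark.parametrize("n", [7, 9, 12])
def test_nj_recovers_additive_matrices_up_to_twelve_leaves(n):
    """On additive input the NJ tree reproduces the matrix exactly, which is
    the zero-SSE least-squares optimum (unique for additive matrices)."""
    rng = np.random.default_rng(200 + n)
    for _ in range(4):
        true_tree = random_additive_tree(n, rng)
        names = sorted(true_tree.leaf_names())
        d = path_matrix(true_tree, names)
        built = nj(names, d)
        assert np.allclose(path_matrix(built, names), d, atol=1e-9)
        assert built.bipartitions() == true_tree.bipartitions()


def test_nj_agrees_with_independent_library_implementation():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(7)
    tree = random_additive_tree(8, rng)
    names = sorted(tree.leaf_names())
    d = path_matrix(tree, names)
    csv = "," + ",".join(names) + "\n"
    for i, nm in enumerate(names):
        csv += nm + "," + ",".join(str(x) for x in d[i]) + "\n"
    import io as _io
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        _io.StringIO(csv), delimiter=",")
    their = pdm.nj_tree()
    their_splits = set()
    all_names = set(names)
    for edge in their.preorder_edge_iter():
        head = edge.head_node
        side = frozenset(l.taxon.label for l in head.leaf_iter())
        if min(all_names) in side:
            side = frozenset(all_names - side)
        if 1 < len(side) < len(all_names) - 1:
            their_splits.add(side)
    assert nj(names, d).bipartitions() == their_splits


def test_non_symmetric_matrix_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        nj(["A", "B", "C"], np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))


def test_negative_branch_estimates_are_clamped_with_raw_retained():
    d = np.array([[0.0, 0.1, 0.4, 0.4], [0.1, 0.0, 0.45, 0.45],
                  [0.4, 0.45, 0.0, 0.05], [0.4, 0.45, 0.05, 0.0]])
    tree = nj(list("ABCD"), d)
    for node in tree.postorder():
        assert node.length >= 0.0
        if node.parent is not None and node.raw_length < 0:
            assert node.length == 0.0


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_perfectly_supported_clade_gets_100():
    aln = {"A": "AAAAAAAA", "B": "AAAAAAAA", "C": "CCCCCCCC",
           "D": "CCCCCCCG"}
    _, support = bootstrap_support(aln, n_reps=50, seed=1)
    assert support[frozenset({"C", "D"})] == 100.0


def test_bootstrap_deterministic_under_fixed_seed():
    rng = np.random.default_rng(0)
    aln = {name: "".join(rng.choice(list("ACGT"), 40)) for name in "ABCDE"}
    _, s1 = bootstrap_support(aln, n_reps=100, seed=9)
    _, s2 = bootstrap_support(aln, n_reps=100, seed=9)
    assert s1 == s2
    assert all(0.0 <= v <= 100.0 for v in s1.values())


def test_conflicting_column_classes_give_intermediate_support():
    # half the columns support AB|CD, half support AC|BD
    col_ab = {"A": "A", "B": "A", "C": "C", "D": "C"}
    col_ac = {"A": "A", "B": "C", "C": "A", "D": "C"}
    aln = {k: col_ab[k] * 20 + col_ac[k] * 20 for k in "ABCD"}
    tree, support = bootstrap_support(aln, n_reps=1000, seed=3)
    (value,) = support.values()
    assert 40.0 < value < 60.0  # ~50% within binomial error at n=1000


# ---------------------------------------------------------------------------
# Rooting and groups
# ---------------------------------------------------------------------------

def test_three_leaf_rooting():
    tree = PhyloTree.from_newick("(A:1,B:1,C:2);")
    rooted = root_with_outgroup(tree, "C")
    top = sorted(tuple(sorted(rooted.leaf_names(c)))
                 for c in rooted.root.children)
    assert top == [("A", "B"), ("C",)]


def test_rooting_preserves_path_lengths_and_is_idempotent():
    rng = np.random.default_rng(12)
    tree = random_additive_tree(8, rng)
    names = sorted(tree.leaf_names())
    before = path_matrix(tree, names)
    rooted = root_with_outgroup(tree, "t5")
    assert np.allclose(path_matrix(rooted, names), before, atol=1e-9)
    again = root_with_outgroup(rooted, "t5")
    assert np.allclose(path_matrix(again, names), before, atol=1e-9)
    assert rooted.bipartitions() == again.bipartitions()


def test_rooting_unknown_leaf_raises():
    with pytest.raises(KeyError):
        root_with_outgroup(PhyloTree.from_newick("(A:1,B:1,C:1);"), "Z")


def test_group_assignment_recovers_planted_clades():
    # four clades hanging off a backbone, two anchors per group
    newick = ("((((a1:.1,a2:.1):.1,a3:.1):.5,((b1:.1,b2:.1):.1,b3:.1):.5):.2,"
              "(((c1:.1,c2:.1):.1,c3:.1):.5,((d1:.1,d2:.1):.1,d3:.1):.5):.2,"
              "out:2.0);")
    rooted = root_with_outgroup(PhyloTree.from_newick(newick), "out")
    anchors = {"1": ["a1", "a3"], "2": ["b1", "b3"],
               "3": ["c1", "c3"], "4": ["d1", "d3"]}
    ga = assign_phylo_groups(rooted, anchors)
    for prefix, group in (("a", "1"), ("b", "2"), ("c", "3"), ("d", "4")):
        for k in "123":
            assert ga.assignment[f"{prefix}{k}"] == group
    assert ga.assignment["out"] == "unassigned"


def test_overlapping_anchor_clades_raise_conflict():
    tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
    with pytest.raises(GroupConflictError):
        assign_phylo_groups(tree, {"1": ["a", "c"], "2": ["b", "d"]})


def test_group_distribution_percentages():
    ga = assign_phylo_groups(
        PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);"),
        {"1": ["a", "b"], "2": ["c", "d"]})
    assert group_distribution(ga) == {"1": 50.0, "2": 50.0}
    assert group_distribution(ga, ["a", "b", "c", "d"]) == \
        {"1": 50.0, "2": 50.0}
    assert group_distribution(ga, ["a", "c", "d"]) == \
        {"1": pytest.approx(33.3), "2": pytest.approx(66.7)}
    with pytest.raises(ValueError):
        group_distribution(ga, [])


def test_group_assignment_invariant_to_leaf_order():
    t1 = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
    t2 = PhyloTree.from_newick("((d:1,c:1):1,(b:1,a:1):1);")
    anchors = {"g": ["a", "b"]}
    assert assign_phylo_groups(t1, anchors).assignment == \
        assign_phylo_groups(t2, anchors).assignment


# ---------------------------------------------------------------------------
# Alternative builders
# ---------------------------------------------------------------------------

def test_upgma_on_ultrametric_matrix():
    d = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
                 dtype=float)
    tree = upgma(list("ABCD"), d)
    assert tree.bipartitions() == {frozenset({"C", "D"})} or \
        tree.bipartitions() == {frozenset({"A", "B"})}
    names, dm = tree.distance_matrix()
    idx = {n: i for i, n in enumerate(names)}
    assert dm[idx["A"], idx["B"]] == pytest.approx(2.0)
    assert dm[idx["C"], idx["D"]] == pytest.approx(4.0)


def test_minimum_evolution_matches_nj_on_additive_input():
    rng = np.random.default_rng(5)
    tree = random_additive_tree(7, rng)
    names = sorted(tree.leaf_names())
    d = path_matrix(tree, names)
    assert minimum_evolution(names, d).bipartitions() == \
        nj(names, d).bipartitions()
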