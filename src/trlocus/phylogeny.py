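"""Distance-based phylogenetics: neighbour joining on p-distances, bootstrap
support, outgroup rooting and assignment of genes to monophyletic groups.

Neighbour joining is the primary builder (exact on additive matrices, with a
deterministic lowest-index tie-break); UPGMA and an NNI-improved
minimum-evolution tree under the ordinary-least-squares length criterion are
provided as robustness checks behind the same interface.  Negative NJ branch
estimates are clamped to zero for display with the raw value retained.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .subgroups import GAP


class Node:
    """Tree node; ``length`` is the (clamped) length of the edge above it."""

    __slots__ = ("name", "length", "raw_length", "support", "children",
                 "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 raw_length: Optional[float] = None,
                 support: Optional[float] = None):
        self.name = name
        self.raw_length = length if raw_length is None else raw_length
        self.length = max(0.0, length)
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Light-weight phylogenetic tree with Newick round-trip."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self, node: Optional[Node] = None) -> Iterable[Node]:
        node = node or self.root
        for child in node.children:
            yield from self.postorder(child)
        yield node

    def leaves(self, node: Optional[Node] = None) -> list[Node]:
        return [n for n in self.postorder(node) if n.is_leaf]

    def leaf_names(self, node: Optional[Node] = None) -> list[str]:
        return [n.name for n in self.leaves(node)]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"unknown leaf {name!r}")

    def mrca(self, names: Iterable[str]) -> Node:
        """Smallest clade containing all ``names`` (rooted semantics)."""
        targets = set(names)
        found = {leaf.name for leaf in self.leaves()} & targets
        if found != targets:
            raise KeyError(f"unknown leaves: {sorted(targets - found)}")
        best = self.root
        improved = True
        while improved:
            improved = False
            for child in best.children:
                if targets <= set(self.leaf_names(child)):
                    best = child
                    improved = True
                    break
        return best

    # -- metrics -----------------------------------------------------------

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (using clamped branch lengths)."""
        leaves = self.leaves()
        names = [l.name for l in leaves]
        n = len(leaves)
        dist = np.zeros((n, n))
        index = {id(l): i for i, l in enumerate(leaves)}
        # accumulate distances from each node down to its leaves
        below: dict[int, dict[int, float]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {index[id(node)]: 0.0}
                continue
            merged: dict[int, float] = {}
            for child in node.children:
                child_map = {k: v + child.length
                             for k, v in below[id(child)].items()}
                for i, di in merged.items():
                    for j, dj in child_map.items():
                        dist[i, j] = dist[j, i] = di + dj
                merged.update(child_map)
            below[id(node)] = merged
        return names, dist

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to the side not containing
        the lexicographically smallest leaf."""
        all_names = set(self.leaf_names())
        anchor = min(all_names)
        splits = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(self.leaf_names(node))
            if anchor in side:
                side = frozenset(all_names - side)
            if 1 < len(side) < len(all_names) - 1:
                splits.add(side)
        return splits

    # -- newick ------------------------------------------------------------

    def newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if supports and node.support is not None:
                    label += format(node.support, "g")
            if lengths and node.parent is not None:
                label += f":{node.length:.6f}"
            return label

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tokens = re.findall(r"[(),;]|[^(),;:]+|:", text.strip())
        pos = 0

        def parse() -> Node:
            nonlocal pos
            node = Node()
            if tokens[pos] == "(":
                pos += 1
                while True:
                    node.add(parse())
                    if tokens[pos] == ",":
                        pos += 1
                        continue
                    break
                assert tokens[pos] == ")", "unbalanced newick"
                pos += 1
                if pos < len(tokens) and tokens[pos] not in "(),;:":
                    try:
                        node.support = float(tokens[pos])
                    except ValueError:
                        node.name = tokens[pos]
                    pos += 1
            else:
                node.name = tokens[pos]
                pos += 1
            if pos < len(tokens) and tokens[pos] == ":":
                pos += 1
                node.raw_length = float(tokens[pos])
                node.length = max(0.0, node.raw_length)
                pos += 1
            return node

        root = parse()
        return cls(root)


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------

def _check_matrix(ids: Sequence[str], d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError("matrix shape does not match taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least two taxa")
    return d


def nj(ids: Sequence[str], d: np.ndarray) -> PhyloTree:
    """Neighbour joining with the lowest-index pair as deterministic
    tie-break.  Returns an unrooted tree (trifurcating root for n >= 3)."""
    d = _check_matrix(ids, d).copy()
    nodes = [Node(name) for name in ids]
    active = list(range(len(ids)))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best, best_q = (i, j), q
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            child.raw_length = length
            child.length = max(0.0, length)
            parent.add(child)
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    root = Node()
    if len(active) == 2:
        i, j = active
        for k in (i, j):
            nodes[k].raw_length = nodes[k].length = d[i, j] / 2
            root.add(nodes[k])
    else:
        i, j, k = active
        for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
            length = 0.5 * (d[a, b] + d[a, c] - d[b, c])
            nodes[a].raw_length = length
            nodes[a].length = max(0.0, length)
            root.add(nodes[a])
    return PhyloTree(root)


def upgma(ids: Sequence[str], d: np.ndarray) -> PhyloTree:
    """Average-linkage (UPGMA) ultrametric tree."""
    d = _check_matrix(ids, d).astype(float).copy()
    clusters: dict[int, Node] = {i: Node(name) for i, name in enumerate(ids)}
    sizes = {i: 1 for i in clusters}
    heights = {i: 0.0 for i in clusters}
    active = list(clusters)
    next_id = len(ids)
    while len(active) > 1:
        best, best_d = None, None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                if best_d is None or d[i, j] < best_d - 1e-12:
                    best, best_d = (i, j), d[i, j]
        i, j = best
        height = best_d / 2
        parent = Node()
        for k in (i, j):
            child = clusters[k]
            child.raw_length = child.length = height - heights[k]
            parent.add(child)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[next_id, k] = d[k, next_id] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (sizes[i] + sizes[j])
        clusters[next_id] = parent
        sizes[next_id] = sizes[i] + sizes[j]
        heights[next_id] = height
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return PhyloTree(clusters[active[0]])


# -- OLS branch fitting and NNI minimum evolution ---------------------------

def _edges(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def ols_fit(tree: PhyloTree, ids: Sequence[str], d: np.ndarray,
            ) -> tuple[float, np.ndarray]:
    """Ordinary-least-squares branch lengths for a fixed topology.

    Returns (sum of squared residuals, fitted edge lengths in postorder)."""
    edges = _edges(tree)
    index = {id(e): k for k, e in enumerate(edges)}
    leaf_sets = {id(e): frozenset(tree.leaf_names(e)) for e in edges}
    names = list(ids)
    pos = {name: i for i, name in enumerate(names)}
    pairs = list(itertools.combinations(names, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (a, b) in enumerate(pairs):
        y[row] = d[pos[a], pos[b]]
        for e in edges:
            inside = leaf_sets[id(e)]
            if (a in inside) != (b in inside):
                A[row, index[id(e)]] = 1.0
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(np.sum((A @ lengths - y) ** 2))
    return sse, lengths


def apply_ols_lengths(tree: PhyloTree, ids: Sequence[str],
                      d: np.ndarray) -> float:
    sse, lengths = ols_fit(tree, ids, d)
    for e, length in zip(_edges(tree), lengths):
        e.raw_length = float(length)
        e.length = max(0.0, float(length))
    return sse


def _nni_neighbourhood(tree: PhyloTree) -> Iterable[PhyloTree]:
    """The trees one nearest-neighbour interchange away."""
    newick = tree.newick(lengths=False, supports=False)
    base = PhyloTree.from_newick(newick)
    internal = [n for n in base.postorder()
                if n.parent is not None and not n.is_leaf]
    for node in internal:
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        for sib in siblings:
            for ci in range(len(node.children)):
                # swap one child of `node` with `sib`
                clone = PhyloTree.from_newick(newick)
                c_node, c_parent = _locate(clone, base, node, parent)
                c_sib = c_parent.children[parent.children.index(sib)]
                c_child = c_node.children[ci]
                pi = c_parent.children.index(c_sib)
                ni = c_node.children.index(c_child)
                c_parent.children[pi], c_node.children[ni] = c_child, c_sib
                c_child.parent, c_sib.parent = c_parent, c_node
                yield clone


def _locate(clone: PhyloTree, base: PhyloTree, node: Node,
            parent: Node) -> tuple[Node, Node]:
    base_nodes = list(base.postorder())
    clone_nodes = list(clone.postorder())
    return (clone_nodes[base_nodes.index(node)],
            clone_nodes[base_nodes.index(parent)])


def minimum_evolution(ids: Sequence[str], d: np.ndarray,
                      max_rounds: int = 20) -> PhyloTree:
    """NJ starting tree improved by NNI under the OLS total-length
    (minimum-evolution) criterion."""
    d = _check_matrix(ids, d)
    tree = nj(ids, d)
    if len(ids) < 4:
        return tree

    def score(t: PhyloTree) -> float:
        _, lengths = ols_fit(t, ids, d)
        return float(np.sum(np.maximum(lengths, 0.0)))

    best, best_score = tree, score(tree)
    for _ in range(max_rounds):
        improved = False
        for candidate in _nni_neighbourhood(best):
            s = score(candidate)
            if s < best_score - 1e-10:
                best, best_score, improved = candidate, s, True
                break
        if not improved:
            break
    apply_ols_lengths(best, ids, d)
    return best


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def alignment_p_distances(alignment: dict[str, str],
                          columns: Optional[np.ndarray] = None,
                          ) -> tuple[list[str], np.ndarray]:
    """p-distance matrix (pairwise deletion) from an aligned set of
    sequences, optionally restricted to a resampled column multiset."""
    ids = list(alignment)
    arr = np.array([list(alignment[i]) for i in ids])
    if columns is not None:
        arr = arr[:, columns]
    n = len(ids)
    d = np.zeros((n, n))
    gaps = arr == GAP
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            sites = int(ok.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = float((arr[i, ok] != arr[j, ok]).sum()) / sites
    return ids, d


def bootstrap_support(alignment: dict[str, str], n_reps: int, seed: int,
                      builder: Callable[[Sequence[str], np.ndarray],
                                        PhyloTree] = nj,
                      ) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Column-resampling bootstrap: percentage of replicate trees containing
    each bipartition of the full-data tree.  Deterministic under a fixed
    seed; supports are attached to the tree's internal nodes."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    n_cols = lengths.pop()
    if n_cols < 1:
        raise ValueError("alignment must have at least one column")
    ids, d = alignment_p_distances(alignment)
    tree = builder(ids, d)
    counts: dict[frozenset, int] = {split: 0 for split in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        _, dr = alignment_p_distances(alignment, columns=cols)
        rep_splits = builder(ids, dr).bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    support = {split: 100.0 * c / n_reps for split, c in counts.items()}
    all_names = set(tree.leaf_names())
    anchor = min(all_names)
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = frozenset(tree.leaf_names(node))
        if anchor in side:
            side = frozenset(all_names - side)
        if side in support:
            node.support = round(support[side], 1)
    return tree, support


# ---------------------------------------------------------------------------
# Rooting and groups
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root on the midpoint of the outgroup's pendant edge.

    Leaf-to-leaf path lengths are preserved; re-rooting an already
    outgroup-rooted tree is a topological no-op.
    """
    work = PhyloTree.from_newick(tree.newick())
    out = work.find_leaf(outgroup_id)
    parent = out.parent
    if parent is None:
        raise ValueError("cannot root a single-leaf tree")
    half = out.length / 2

    parent.children.remove(out)
    out.parent = None

    # reverse the path parent -> ... -> old root so `parent` hangs off the
    # new root; edge lengths/supports travel with their edges
    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = node.parent
    original = [(n.length, n.raw_length, n.support) for n in path]
    for i in range(1, len(path)):
        upper, lower = path[i], path[i - 1]
        upper.children.remove(lower)
        upper.parent = lower
        # the edge between lower and upper was stored on lower; after the
        # flip it is stored on upper
        upper.length, upper.raw_length, upper.support = original[i - 1]
        lower.children.append(upper)
    # splice out degree-2 remnants of the old root along the path
    for node in path:
        for child in list(node.children):
            if not child.is_leaf and len(child.children) == 1:
                grand = child.children[0]
                grand.length += child.length
                grand.raw_length = (grand.raw_length or 0) + child.raw_length
                grand.parent = node
                node.children[node.children.index(child)] = grand

    root = Node()
    out.length = out.raw_length = half
    parent.length = parent.raw_length = half
    parent.support = None
    root.add(out)
    root.add(parent)
    return PhyloTree(root)


@dataclass
class GroupAssignment:
    """Gene -> phylogenetic group map from anchor-defined clades."""

    assignment: dict[str, str]
    anchors: dict[str, set] = field(default_factory=dict)


class GroupConflictError(ValueError):
    """Anchor clades overlap or nest; carries the offending group pairs."""

    def __init__(self, conflicts: list[tuple[str, str, list[str]]]):
        self.conflicts = conflicts
        msg = "; ".join(f"groups {a}/{b} share leaves {shared[:5]}"
                        for a, b, shared in conflicts)
        super().__init__(f"anchor clades are not disjoint: {msg}")


def assign_phylo_groups(tree: PhyloTree,
                        anchors: dict[str, Iterable[str]]) -> GroupAssignment:
    """Each group is the smallest clade of the rooted tree containing all of
    its anchor leaves; leaves inside no anchor clade stay unassigned."""
    anchor_sets = {g: set(a) for g, a in anchors.items()}
    for (g1, s1), (g2, s2) in itertools.combinations(anchor_sets.items(), 2):
        if s1 & s2:
            raise GroupConflictError([(g1, g2, sorted(s1 & s2))])
    clades = {}
    for group, names in anchor_sets.items():
        clades[group] = set(tree.leaf_names(tree.mrca(names)))
    conflicts = [(g1, g2, sorted(clades[g1] & clades[g2]))
                 for g1, g2 in itertools.combinations(clades, 2)
                 if clades[g1] & clades[g2]]
    if conflicts:
        raise GroupConflictError(conflicts)
    assignment = {}
    for leaf in tree.leaf_names():
        assignment[leaf] = "unassigned"
        for group, clade in clades.items():
            if leaf in clade:
                assignment[leaf] = group
                break
    return GroupAssignment(assignment=assignment, anchors=anchor_sets)


def group_distribution(assignment: GroupAssignment,
                       subset: Optional[Iterable[str]] = None,
                       ) -> dict[str, float]:
    """Percentage of genes per group over ``subset`` (default: all leaves)."""
    genes = list(subset) if subset is not None else list(assignment.assignment)
    if not genes:
        raise ValueError("empty gene subset")
    counts: dict[str, int] = {}
    for gene in genes:
        group = assignment.assignment.get(gene, "unassigned")
        counts[group] = counts.get(group, 0) + 1
    return {group: round(100.0 * c / len(genes), 1)
            for group, c in sorted(counts.items())}
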