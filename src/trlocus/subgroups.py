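"""Pairwise nucleotide identity, subgroup clustering at the 75% convention,
and orthology-based subgroup naming.

V-gene subgroups are conventionally defined as sets of genes sharing >= 75%
nucleotide identity.  Identity here is computed per pair from a global
alignment (match +1, mismatch -1, gap open -4, gap extend -1) followed by
pairwise deletion of gap columns — deterministic and self-contained, with no
multiple alignment step.  Clustering takes the connected components of the
">= threshold" graph and reports convention violations (within-cluster pairs
below threshold reached through transitivity, and near-threshold
cross-cluster pairs) instead of adjudicating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

GAP = "-"


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing sites under pairwise deletion.

    Both sequences must be aligned (equal length, '-' for gaps); columns
    where either sequence has a gap are excluded from the denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    sites = diffs = 0
    for a, b in zip(seq_a, seq_b):
        if a == GAP or b == GAP:
            continue
        sites += 1
        if a != b:
            diffs += 1
    if sites == 0:
        raise ValueError("no comparable sites (pairwise deletion removed all)")
    return diffs / sites


def comparable_sites(seq_a: str, seq_b: str) -> int:
    return sum(1 for a, b in zip(seq_a, seq_b) if a != GAP and b != GAP)


_nt_aligner: Optional[Align.PairwiseAligner] = None


def nucleotide_aligner() -> Align.PairwiseAligner:
    global _nt_aligner
    if _nt_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -1.0
        _nt_aligner = aligner
    return _nt_aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment of two nucleotide sequences; returns gapped strings."""
    if seq_a == seq_b:
        return seq_a, seq_b
    alignment = nucleotide_aligner().align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    return p_distance(*align_pair(seq_a, seq_b))


@dataclass
class IdentityMatrix:
    """Symmetric p-distance matrix with pairwise-deletion site counts."""

    ids: list[str]
    distances: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric, zero-diagonal")
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    @property
    def identity(self) -> np.ndarray:
        return 1.0 - self.distances

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.identity, index=self.ids, columns=self.ids)


def identity_matrix(seqs: dict[str, str]) -> IdentityMatrix:
    """All-pairs identity from per-pair global alignments."""
    ids = list(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        sites[i, i] = len(seqs[ids[i]])
        for j in range(i + 1, n):
            a, b = align_pair(seqs[ids[i]], seqs[ids[j]])
            d[i, j] = d[j, i] = p_distance(a, b)
            sites[i, j] = sites[j, i] = comparable_sites(a, b)
    return IdentityMatrix(ids=ids, distances=d, sites=sites)


@dataclass
class SubgroupCluster:
    label: str
    members: list[str]
    diagnostics: dict = field(default_factory=dict)


def cluster_by_identity(matrix: IdentityMatrix,
                        threshold: float = 0.75) -> list[SubgroupCluster]:
    """Connected components of the ">= threshold identity" graph.

    Diagnostics per cluster: the minimum within-cluster identity,
    within-cluster pairs falling below the threshold (reached transitively),
    and cross-cluster pairs within two percentage points of the threshold.
    """
    n = len(matrix.ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ident = matrix.identity
    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: min(g))

    clusters = []
    membership = {}
    for k, idxs in enumerate(ordered):
        for i in idxs:
            membership[i] = k
    for k, idxs in enumerate(ordered):
        below = [(matrix.ids[i], matrix.ids[j], round(ident[i, j], 4))
                 for ai, i in enumerate(idxs) for j in idxs[ai + 1:]
                 if ident[i, j] < threshold]
        min_within = (min(ident[i, j] for ai, i in enumerate(idxs)
                          for j in idxs[ai + 1:])
                      if len(idxs) > 1 else 1.0)
        clusters.append(SubgroupCluster(
            label=f"cluster{k + 1}",
            members=[matrix.ids[i] for i in idxs],
            diagnostics={"min_within_identity": round(float(min_within), 4),
                         "below_threshold_pairs": below,
                         "near_threshold_cross_pairs": []}))
    for i in range(n):
        for j in range(i + 1, n):
            if membership[i] != membership[j] and \
                    threshold - 0.02 <= ident[i, j] < threshold:
                pair = (matrix.ids[i], matrix.ids[j], round(ident[i, j], 4))
                clusters[membership[i]].diagnostics[
                    "near_threshold_cross_pairs"].append(pair)
                clusters[membership[j]].diagnostics[
                    "near_threshold_cross_pairs"].append(pair)
    return clusters


# ---------------------------------------------------------------------------
# Orthology-based naming
# ---------------------------------------------------------------------------

def _alphabetic_names():
    letters = "XYZABCDEFGHIJKLMNOPQRSTUVW"
    for letter in letters:
        yield letter
    i = 2
    while True:
        for letter in letters:
            yield f"{letter}{i}"
        i += 1


@dataclass
class NamedCluster:
    cluster: SubgroupCluster
    name: str
    basis: str  # 'orthology' | 'alphabetic'
    mean_identity: float
    conflicts: list[str] = field(default_factory=list)


def assign_orthologous_names(
        clusters: Sequence[SubgroupCluster],
        reference_catalogs: dict[str, dict[str, str]],
        cluster_seqs: dict[str, str],
        joint_tree=None,
        identity_floor: float = 0.631) -> list[NamedCluster]:
    """Name clusters after orthologous reference subgroups.

    A cluster takes a reference subgroup's name when its mean identity to
    that subgroup's sequences is maximal among references and at least
    ``identity_floor``, and (when a rooted ``joint_tree`` over cluster
    members plus reference ids is supplied) the cluster is monophyletic with
    that reference.  Otherwise the cluster receives an alphabetic
    designation (X, Y, ...), issued in order of each cluster's first member.
    If two clusters claim the same reference name, the higher mean identity
    keeps it; both claims are reported.
    """
    candidates = []
    for cluster in clusters:
        best_name, best_ident = None, -1.0
        for ref_name, ref_seqs in reference_catalogs.items():
            idents = [1.0 - pairwise_p_distance(cluster_seqs[m], rseq)
                      for m in cluster.members for rseq in ref_seqs.values()]
            mean_ident = float(np.mean(idents)) if idents else 0.0
            if mean_ident > best_ident:
                best_name, best_ident = ref_name, mean_ident
        ok = best_name is not None and best_ident >= identity_floor
        if ok and joint_tree is not None:
            ref_ids = set(reference_catalogs[best_name])
            ok = _monophyletic_with(joint_tree, set(cluster.members), ref_ids)
        candidates.append((cluster, best_name if ok else None, best_ident))

    # resolve duplicate claims: higher mean identity wins
    claimed: dict[str, tuple[int, float]] = {}
    conflicts: dict[int, list[str]] = {}
    for idx, (cluster, name, ident) in enumerate(candidates):
        if name is None:
            continue
        if name in claimed:
            other_idx, other_ident = claimed[name]
            loser = idx if ident <= other_ident else other_idx
            winner = other_idx if loser == idx else idx
            conflicts.setdefault(loser, []).append(
                f"lost claim to {name} (mean identity "
                f"{candidates[loser][2]:.3f} < {candidates[winner][2]:.3f})")
            conflicts.setdefault(winner, []).append(
                f"contested claim to {name}")
            candidates[loser] = (candidates[loser][0], None,
                                 candidates[loser][2])
            if winner == idx:
                claimed[name] = (idx, ident)
        else:
            claimed[name] = (idx, ident)

    order = {id(c): i for i, c in enumerate(clusters)}
    alphabet = _alphabetic_names()
    named = []
    for idx, (cluster, name, ident) in enumerate(candidates):
        if name is None:
            name, basis = next(alphabet), "alphabetic"
        else:
            basis = "orthology"
        named.append(NamedCluster(cluster=cluster, name=name, basis=basis,
                                  mean_identity=round(ident, 4),
                                  conflicts=conflicts.get(idx, [])))
    named.sort(key=lambda nc: order[id(nc.cluster)])
    return named


def _monophyletic_with(tree, members: set[str], ref_ids: set[str]) -> bool:
    """True when the smallest clade holding the cluster plus the reference
    contains no other leaves."""
    target = members | ref_ids
    node = tree.mrca(target)
    return set(tree.leaf_names(node)) <= target


def clusters_table(named: Sequence[NamedCluster]) -> pd.DataFrame:
    rows = []
    for nc in named:
        rows.append({"cluster": nc.cluster.label, "name": nc.name,
                     "basis": nc.basis, "mean_identity": nc.mean_identity,
                     "n_members": len(nc.cluster.members),
                     "members": ";".join(nc.cluster.members),
                     "min_within_identity":
                         nc.cluster.diagnostics.get("min_within_identity"),
                     "n_below_threshold_pairs":
                         len(nc.cluster.diagnostics.get(
                             "below_threshold_pairs", []))})
    return pd.DataFrame(rows)
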