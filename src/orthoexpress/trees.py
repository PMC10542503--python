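"""Alignment-free gene trees and genus-monophyly tests.

Orthogroups can contain paralogs; in a gene tree a genus whose
transcripts are *not* monophyletic is the signature of paralog
contamination.  Distances between transcripts are alignment-free
(1 - cosine similarity of k-mer count vectors, k = 6 by default), the
tree is built by neighbor joining, and monophyly of a genus is read off
the tree's bipartitions, which is equivalent to rooting on any leaf
outside the genus.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

__all__ = [
    "kmer_counts",
    "kmer_distance_matrix",
    "neighbor_joining",
    "genus_monophyly",
    "tip_bipartitions",
]


def kmer_counts(sequence: str, k: int = 6) -> dict[str, int]:
    """Overlapping k-mer counts of one sequence."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than k={k}")
    counts: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_distance_matrix(
    sequences: Mapping[str, str] | Sequence[str], k: int = 6
) -> tuple[np.ndarray, list[str]]:
    """Pairwise 1 - cosine distances of k-mer count vectors.

    Returns the symmetric matrix (zero diagonal) and the label order.
    """
    if isinstance(sequences, Mapping):
        labels = list(sequences)
        seqs = [sequences[l] for l in labels]
    else:
        seqs = list(sequences)
        labels = [str(i) for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    profiles = [kmer_counts(s, k) for s in seqs]
    vocab = sorted(set().union(*profiles))
    idx = {w: i for i, w in enumerate(vocab)}
    mat = np.zeros((len(seqs), len(vocab)))
    for r, prof in enumerate(profiles):
        for w, c in prof.items():
            mat[r, idx[w]] = c
    norm = np.linalg.norm(mat, axis=1)
    sim = (mat @ mat.T) / np.outer(norm, norm)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    return dist, labels


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return d


def neighbor_joining(distances: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree (Q-matrix agglomeration).

    Deterministic tie-break: the smallest (i, j) index pair wins.
    Negative branch lengths are clamped to zero.  The returned tree is
    unrooted, represented with a trifurcating root (n >= 3 leaves).
    """
    d = _check_distance_matrix(distances).copy()
    n = d.shape[0]
    if n != len(labels):
        raise ValueError("labels must match the distance matrix dimension")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    nodes: list[TreeNode] = [TreeNode(name=str(l)) for l in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties resolved by smallest (i, j)
        flat = np.argmin(q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        limb_i = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        child_i, child_j = nodes[active[i]], nodes[active[j]]
        child_i.length = max(float(limb_i), 0.0)
        child_j.length = max(float(limb_j), 0.0)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining actives
        others = [a for idx, a in enumerate(active) if idx not in (i, j)]
        ai, aj = active[i], active[j]
        new_idx = ai  # reuse slot i
        for a in others:
            d[new_idx, a] = d[a, new_idx] = 0.5 * (d[ai, a] + d[aj, a] - dij)
        nodes[new_idx] = parent
        active = [a for a in active if a != aj]
        active[active.index(ai)] = new_idx
    # final three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, length in zip((a, b, c), (la, lb, lc)):
        nodes[node].length = max(float(length), 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def tip_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Tip-name subsets induced by every internal edge of the tree."""
    subsets: set[frozenset[str]] = set()
    for node in tree.postorder(include_self=False):
        if not node.is_tip():
            subsets.add(frozenset(t.name for t in node.tips()))
    return subsets


def genus_monophyly(
    tree: TreeNode,
    genus_of: Mapping[str, str],
    genera: Iterable[str] | None = None,
) -> dict[str, bool]:
    """Is each genus's leaf set a clade?

    A genus is monophyletic when its leaves form one side of a tree
    bipartition (for a tree rooted on a leaf of any other genus this is
    exactly the rooted clade criterion; with no outside leaf the test is
    vacuous).  Genera with <= 1 leaf are vacuously monophyletic.
    """
    tips = [t.name for t in tree.tips()]
    tipset = frozenset(tips)
    missing = [t for t in tips if t not in genus_of]
    if missing:
        raise KeyError(f"no genus assignment for leaves {missing[:3]}")
    if genera is None:
        genera = sorted(set(genus_of[t] for t in tips))
    subsets = tip_bipartitions(tree)
    result: dict[str, bool] = {}
    for genus in genera:
        members = frozenset(t for t in tips if genus_of[t] == genus)
        if not members:
            raise KeyError(f"genus {genus!r} absent from tree")
        if len(members) <= 1 or members == tipset:
            result[genus] = True
            continue
        complement = tipset - members
        if len(complement) <= 1:
            # rooting on the single outside leaf makes the genus a clade
            result[genus] = True
            continue
        result[genus] = members in subsets or complement in subsets
    return result
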