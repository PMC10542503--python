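"""Orthogroup parsing, one-to-one extraction, NJ trees and the
monophyly-based paralog filter."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from orthoexpress import (
    Orthogroup,
    OgMember,
    filter_paralogous_orthogroups,
    genus_monophyly,
    kmer_distance_matrix,
    neighbor_joining,
    one_to_one_orthogroups,
    parse_orthogroups,
    simulate_orthogroup_sequences,
    size_summary,
)
from orthoexpress.orthogroups import write_orthogroups
from orthoexpress.trees import kmer_counts


def test_parse_row_with_lists_and_empty_cells():
    text = "Orthogroup\tA\tB\tC\nOG1\ta1, a2\t\tc1\n"
    ogs = parse_orthogroups(io.StringIO(text), taxon_to_genus={"A": "GA", "B": "GB", "C": "GC"})
    assert len(ogs) == 1
    og = ogs[0]
    assert og.size == 3
    assert og.taxa == {"A", "C"}
    assert {m.genus for m in og.members} == {"GA", "GC"}


def test_parse_skips_empty_rows_and_rejects_duplicates():
    with pytest.warns(UserWarning):
        ogs = parse_orthogroups(io.StringIO("Orthogroup\tA\nOG1\ta1\n\tb1\n"))
    assert [og.id for og in ogs] == ["OG1"]
    with pytest.raises(ValueError, match="duplicate"):
        parse_orthogroups(io.StringIO("Orthogroup\tA\nOG1\ta1\nOG1\ta2\n"))


def test_orthogroup_write_parse_round_trip(tmp_path, rng):
    taxa = ["bro", "fru", "sun", "lem"]
    ogs = []
    for i in range(50):
        members = []
        for t in taxa:
            for j in range(int(rng.integers(0, 4))):
                members.append(OgMember(f"og{i}_{t}_{j}", t))
        if members:
            ogs.append(Orthogroup(id=f"OG{i:04d}", members=members))
    path = tmp_path / "ogs.tsv"
    write_orthogroups(ogs, path, taxa=taxa)
    back = parse_orthogroups(path)
    assert [og.id for og in back] == [og.id for og in ogs]
    for a, b in zip(ogs, back):
        assert [(m.transcript, m.taxon) for m in a.members] == [
            (m.transcript, m.taxon) for m in b.members
        ]


def test_one_to_one_extraction():
    taxa = ("bro", "fru", "sun", "lem")
    good = Orthogroup("OGa", [OgMember(f"a_{t}", t) for t in taxa])
    missing = Orthogroup("OGb", [OgMember(f"b_{t}", t) for t in taxa[:3]])
    extra = Orthogroup(
        "OGc", [OgMember(f"c_{t}", t) for t in taxa] + [OgMember("c_x", "bro")]
    )
    other = Orthogroup(
        "OGd", [OgMember(f"d_{t}", t) for t in taxa] + [OgMember("d_h", "hel")]
    )
    kept = one_to_one_orthogroups([good, missing, extra, other], taxa)
    assert [og.id for og in kept] == ["OGa"]


def test_one_to_one_count_matches_construction(rng):
    taxa = ("bro", "fru", "sun", "lem")
    ogs = []
    n_true = 0
    for i in range(1000):
        one_to_one = i % 8 == 0  # 125 by construction
        if one_to_one:
            members = [OgMember(f"g{i}_{t}", t) for t in taxa]
            n_true += 1
        else:
            members = [OgMember(f"g{i}_{t}", t) for t in taxa]
            members.append(OgMember(f"g{i}_dup", taxa[int(rng.integers(4))]))
        ogs.append(Orthogroup(f"OG{i}", members))
    assert len(one_to_one_orthogroups(ogs, taxa)) == n_true


def test_kmer_distance_trivial_cases():
    d, _ = kmer_distance_matrix({"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"}, k=6)
    assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
    # disjoint k-mer sets
    d2, _ = kmer_distance_matrix({"a": "AAAAAAAA", "b": "CCCCCCCC"}, k=6)
    assert d2[0, 1] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        kmer_distance_matrix({"a": "ACGT", "b": "ACGTACGT"}, k=6)


def test_kmer_matrix_matches_brute_force_cosine(rng):
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(10)
    }
    d, labels = kmer_distance_matrix(seqs, k=6)
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            ci, cj = kmer_counts(seqs[li], 6), kmer_counts(seqs[lj], 6)
            dot = sum(ci[w] * cj.get(w, 0) for w in ci)
            ni = np.sqrt(sum(v * v for v in ci.values()))
            nj = np.sqrt(sum(v * v for v in cj.values()))
            expect = 0.0 if i == j else 1.0 - dot / (ni * nj)
            assert d[i, j] == pytest.approx(expect, abs=1e-12)


def test_three_leaf_nj_uses_closed_form():
    d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 10.0], [9.0, 10.0, 0.0]])
    tree = neighbor_joining(d, ["a", "b", "c"])
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths, plus its
    leaf-to-leaf path-distance matrix."""
    labels = [f"t{i}" for i in range(n_leaves)]
    nodes = {l: TreeNode(name=l, length=None) for l in labels}
    # random sequential joins
    active = labels[:]
    dist = {(a, b): 0.0 for a in labels for b in labels}
    parent_dist = {l: 0.0 for l in labels}
    # build by random coalescence, tracking tip depths under each node
    groups = {l: [l] for l in labels}
    depth = {l: {l: 0.0} for l in labels}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0)
        nodes[a].length, nodes[b].length = la, lb
        new = f"n{len(nodes)}"
        nodes[new] = TreeNode(name=None, children=[nodes[a], nodes[b]])
        for ta, da in depth[a].items():
            for tb, db in depth[b].items():
                dist[(ta, tb)] = dist[(tb, ta)] = da + la + db + lb
        depth[new] = {t: d + la for t, d in depth[a].items()}
        depth[new].update({t: d + lb for t, d in depth[b].items()})
        del depth[a], depth[b]
        active = [x for x in active if x not in (a, b)] + [new]
    root = nodes[active[0]]
    mat = np.array([[dist[(a, b)] if a != b else 0.0 for b in labels] for a in labels])
    return root, labels, mat


def bipartition_set(tree):
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            out.add(frozenset((side, tips - side)))
    return out


def test_nj_recovers_topology_from_additive_distances(rng):
    for _ in range(50):
        n = int(rng.integers(6, 9))
        true_tree, labels, mat = random_additive_tree(rng, n)
        nj = neighbor_joining(mat, labels)
        assert bipartition_set(nj) == bipartition_set(true_tree)


def test_nj_is_invariant_to_leaf_permutation(rng):
    _, labels, mat = random_additive_tree(rng, 7)
    base = bipartition_set(neighbor_joining(mat, labels))
    perm = rng.permutation(len(labels))
    permuted = bipartition_set(
        neighbor_joining(mat[np.ix_(perm, perm)], [labels[i] for i in perm])
    )
    assert base == permuted


def test_nj_agrees_with_reference_implementation(rng):
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    for _ in range(5):
        _, labels, mat = random_additive_tree(rng, 7)
        ours = bipartition_set(neighbor_joining(mat, labels))
        ref = bipartition_set(skbio_nj(DistanceMatrix(mat, labels)))
        assert ours == ref


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
    with pytest.raises(ValueError):
        neighbor_joining(np.zeros((2, 2)), ["a", "b"])


def test_monophyly_on_hand_built_trees():
    clean = TreeNode.read(io.StringIO("((g1a:1,g1b:1):1,(g2a:1,g2b:1):1);"))
    genus_of = {"g1a": "G1", "g1b": "G1", "g2a": "G2", "g2b": "G2"}
    assert genus_monophyly(clean, genus_of) == {"G1": True, "G2": True}

    mixed = TreeNode.read(io.StringIO("((g1a:1,g2a:1):1,(g1b:1,g2b:1):1);"))
    result = genus_monophyly(mixed, genus_of)
    assert result == {"G1": False, "G2": False}

    with pytest.raises(KeyError):
        genus_monophyly(clean, genus_of, genera=["G3"])


def test_filter_keeps_everything_on_clean_orthogroups():
    ogs, truth = simulate_orthogroup_sequences(40, paralog_fraction=0.0, seed=3)
    assert not truth["contaminated"].any()
    kept, removed, report = filter_paralogous_orthogroups(ogs)
    assert removed == []
    assert report.n_kept == 40


def test_filter_partitions_the_input():
    ogs, _ = simulate_orthogroup_sequences(30, paralog_fraction=0.3, seed=4)
    # make a few orthogroups untestable
    ogs[0].sequences = None
    small = Orthogroup("OGsmall", [OgMember("s1", "bro", "Argyranthemum"),
                                   OgMember("s2", "hel", "Helianthus")],
                       sequences={"s1": "ACGTACGTACGT", "s2": "ACGTACGTACGT"})
    ogs.append(small)
    kept, removed, report = filter_paralogous_orthogroups(ogs)
    assert len(kept) + len(removed) == len(ogs)
    assert report.n_input == len(ogs)
    assert report.n_kept == len(kept)
    assert report.n_untested >= 2
    statuses = report.per_orthogroup["status"]
    assert (statuses.value_counts().get("removed", 0)) == len(removed)


def test_size_summary_examples_and_random_tally(rng):
    def og_of_size(i, n):
        return Orthogroup(f"OG{i}", [OgMember(f"m{i}_{j}", "bro") for j in range(n)])

    singles = [og_of_size(i, 1) for i in range(5)]
    assert size_summary(singles) == {5: 1.0, 10: 1.0}
    mixed = [og_of_size(0, 2), og_of_size(1, 6), og_of_size(2, 11)]
    frac = size_summary(mixed)
    assert frac[5] == pytest.approx(1 / 3)
    assert frac[10] == pytest.approx(2 / 3)
    sizes = rng.integers(1, 20, size=100)
    ogs = [og_of_size(i, int(s)) for i, s in enumerate(sizes)]
    frac = size_summary(ogs, thresholds=(5, 10))
    assert frac[5] == pytest.approx((sizes <= 5).mean())
    assert frac[10] == pytest.approx((sizes <= 10).mean())
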