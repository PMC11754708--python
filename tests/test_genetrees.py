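"""Distances, neighbor joining, cophenetic matrices and the CPD test."""

import numpy as np
import pytest

from transpoly import genetrees as gt
from transpoly.io_core import HaplotypeAlignment, tree_from_newick


def test_pairwise_distances_basic():
    aln = HaplotypeAlignment(names=["a", "b", "c"],
                             sequences=["AAAA", "AAAT", "AANT"])
    d = gt.pairwise_distances(aln)
    assert d.matrix[0, 0] == 0.0
    assert d.matrix[0, 1] == pytest.approx(0.25)
    # N sites excluded pairwise: b vs c compared over 3 sites, 0 mismatches
    assert d.matrix[1, 2] == pytest.approx(0.0)


def test_jc69_undefined_beyond_saturation():
    aln = HaplotypeAlignment(names=["a", "b"],
                             sequences=["AAAA", "TTTT"])
    with pytest.raises(ValueError, match="JC69"):
        gt.pairwise_distances(aln, model="jc69")


def test_nj_recovers_additive_tree_exactly():
    """Cophenetic distances of a 4-taxon tree are additive; NJ must invert
    them to the generating topology and branch lengths."""
    source = tree_from_newick("((a:1.0,b:2.0):1.5,(c:0.5,d:3.0):1.0);")
    cd = gt.cophenetic(source)
    tree = gt.nj_tree(cd)
    cd2 = gt.cophenetic(tree)
    assert cd2.labels == cd.labels
    np.testing.assert_allclose(cd2.matrix, cd.matrix, atol=1e-9)
    # topology check: a,b are siblings
    taxa = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    sib_labels = {c.taxon.label for c in taxa["a"].parent_node.leaf_iter()}
    assert sib_labels == {"a", "b"}


def test_nj_star_matrix_preserves_equidistance():
    labels = ["a", "b", "c", "d"]
    m = np.full((4, 4), 2.0)
    np.fill_diagonal(m, 0.0)
    tree = gt.nj_tree(gt.DistanceMatrix(labels=labels, matrix=m))
    cd = gt.cophenetic(tree)
    np.testing.assert_allclose(cd.matrix, m, atol=1e-12)


def test_nj_requires_three_taxa():
    m = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match=">= 3"):
        gt.nj_tree(gt.DistanceMatrix(labels=["a", "b"], matrix=m))


def test_cophenetic_hand_examples():
    d1 = gt.cophenetic(tree_from_newick("(a:1,b:2);"))
    assert d1.matrix[d1.labels.index("a"), d1.labels.index("b")] == 3.0
    d2 = gt.cophenetic(tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);"))
    i = {lab: k for k, lab in enumerate(d2.labels)}
    assert d2.matrix[i["a"], i["c"]] == 4.0
    assert d2.matrix[i["a"], i["b"]] == 2.0


def brute_force_path_lengths(tree):
    """Independent oracle: tip-to-tip distances by explicit path walks."""
    import itertools
    dist = {}
    leaves = list(tree.leaf_node_iter())
    for u, v in itertools.combinations(leaves, 2):
        anc_u = {}
        node, acc = u, 0.0
        while node is not None:
            anc_u[id(node)] = acc
            acc += node.edge.length or 0.0
            node = node.parent_node
        node, acc = v, 0.0
        while id(node) not in anc_u:
            acc += node.edge.length or 0.0
            node = node.parent_node
        dist[frozenset((u.taxon.label, v.taxon.label))] = acc + anc_u[id(node)]
    return dist


def test_cophenetic_matches_brute_force_on_random_trees():
    rng = np.random.default_rng(13)
    for seed in range(3):
        # random binary tree via random NJ input
        n = 8
        m = rng.random((n, n)) * 2
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(n)]
        tree = gt.nj_tree(gt.DistanceMatrix(labels=labels, matrix=m))
        cd = gt.cophenetic(tree)
        oracle = brute_force_path_lengths(tree)
        for key, val in oracle.items():
            a, b = sorted(key)
            got = cd.matrix[cd.labels.index(a), cd.labels.index(b)]
            assert got == pytest.approx(val, abs=1e-9)


def test_cpd_hand_computed_deltas():
    species = lambda lab: lab[0]
    res = gt.cpd_test(tree_from_newick("((A1:1,A2:1):2,(B1:1,B2:1):2);"),
                      species)
    assert (res.cpd_within, res.cpd_between) == (2.0, 6.0)
    assert res.delta == -4.0 and res.call == "SPECIES_TREE"

    res2 = gt.cpd_test(tree_from_newick("((A1:1,B1:1):2,(A2:1,B2:1):2);"),
                       species)
    assert (res2.cpd_within, res2.cpd_between) == (6.0, 4.0)
    assert res2.delta == 2.0 and res2.call == "TRANS_SPECIFIC"


def test_cpd_tie_and_scaling_invariance():
    species = lambda lab: lab[0]
    tie_tree = tree_from_newick("((A1:1,B1:1):0,(A2:1,B2:1):0);")
    assert gt.cpd_test(tie_tree, species).call == "TIE"

    base = tree_from_newick("((A1:1,A2:1):2,(B1:1,B2:1):2);")
    scaled = tree_from_newick("((A1:10,A2:10):20,(B1:10,B2:10):20);")
    r1, r2 = gt.cpd_test(base, species), gt.cpd_test(scaled, species)
    assert r1.call == r2.call
    assert r2.delta == pytest.approx(10 * r1.delta)


def test_cpd_requires_two_tips_per_species():
    species = lambda lab: lab[0]
    with pytest.raises(ValueError, match="2 tips"):
        gt.cpd_test(tree_from_newick("((A1:1,B1:1):1,B2:1);"), species)


def test_extract_windows_filters_and_contents():
    from transpoly import classify
    from transpoly.simulate import (BalancedLocusConfig, SplitSimConfig,
                                    genotype_matrix_from_alignment,
                                    sim_balanced_trans_locus)

    split = SplitSimConfig(T_split=2.0, theta=5.0, locus_len=500)
    aln, gm, info = sim_balanced_trans_locus(
        BalancedLocusConfig(seed=21, flank_len=500), split)
    cls = classify.classify_sites(gm, "A", "B", maf_min=0.01)
    windows = gt.extract_windows(aln, gm, cls, flank=100, maf_min=0.25,
                                 n_per_species=5)
    assert windows, "no focal SNPs found"
    focal_positions = {w.focal_pos for w in windows}
    assert focal_positions <= set(info["trans_positions"])
    for w in windows:
        assert len(w.alignment) == 2 * 2 * 5  # both haplotypes, 5 per species
        if not w.truncated:
            # inclusive window [pos - flank/2, pos + flank/2]
            assert w.alignment.length == 101
    # low-frequency shared SNPs are not focal
    low = cls[(cls["label"] == "SHARED_POLY")]
    maf = np.minimum(low["freq_a"], 1 - low["freq_a"])
    excluded = set(low.loc[maf <= 0.25, "pos"])
    assert not (focal_positions & excluded)
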