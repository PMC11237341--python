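"""Distances, neighbor joining, bootstrap and clade checks."""

import math
import random

import dendropy
import numpy as np
import pytest

from mitochar.io_formats import AlignmentBlock
from mitochar.phylo import (
    DistanceMatrix,
    bootstrap,
    build_gene_alignments,
    check_clades,
    concatenate_pcgs,
    distance_matrix,
    nj_tree,
    robinson_foulds,
)


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a.label, b.label)] = pdm.distance(a, b)
    return out


def random_binary_tree(n, rng):
    tns = dendropy.TaxonNamespace([f"x{i}" for i in range(n)])
    nodes = []
    for t in tns:
        nd = dendropy.Node()
        nd.taxon = t
        nd.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(nd)
    while len(nodes) > 2:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        p = dendropy.Node()
        p.add_child(a)
        p.add_child(b)
        p.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(p)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def dm_from_tree(tree):
    taxa = sorted(t.label for t in tree.taxon_namespace)
    pd = patristic(tree)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pd[(taxa[i], taxa[j])]
    return DistanceMatrix(taxa, d, np.zeros((n, n), dtype=bool))


def test_distance_models_closed_forms():
    # 10% mismatches, all transversion-free patterns avoided for p/JC
    row_a = "A" * 100
    row_b = "C" * 10 + "A" * 90  # transversions
    a = AlignmentBlock(["a", "b"], [row_a, row_b])
    p = distance_matrix(a, "p").d[0, 1]
    assert p == pytest.approx(0.10)
    jc = distance_matrix(a, "JC69").d[0, 1]
    assert jc == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3), abs=1e-6)
    assert jc == pytest.approx(0.1073, abs=1e-3)
    # transitions only: K2P reduces to -0.5 ln(1 - 2P)
    row_c = "G" * 10 + "A" * 90
    b = AlignmentBlock(["a", "c"], [row_a, row_c])
    k2p = distance_matrix(b, "K2P").d[0, 1]
    assert k2p == pytest.approx(-0.5 * math.log(1 - 0.2), abs=1e-9)


def test_distance_identical_rows_zero_and_gap_deletion():
    a = AlignmentBlock(["a", "b"], ["ACGTACGT", "ACGT--GT"])
    d = distance_matrix(a, "p")
    assert d.d[0, 1] == 0.0
    with pytest.raises(ValueError):
        distance_matrix(AlignmentBlock(["a", "b"], ["AAAA", "----"]), "p")


def test_distance_saturation_flagged():
    a = AlignmentBlock(["a", "b"], ["A" * 10, "C" * 10])
    d = distance_matrix(a, "JC69")
    assert d.flagged[0, 1]
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b", "c"],
                               np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]),
                               np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=bool)))


def test_nj_three_taxon_closed_form():
    d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]])
    dm = DistanceMatrix(["A", "B", "C"], d, np.zeros((3, 3), dtype=bool))
    tree = nj_tree(dm)
    pd = patristic(tree)
    assert pd[("A", "B")] == pytest.approx(2)
    assert pd[("A", "C")] == pytest.approx(3)
    assert pd[("B", "C")] == pytest.approx(4)


def test_nj_recovers_additive_quartet_exactly():
    # ((A:1,B:2):3,(C:4,D:5)) -> additive distances
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0.0]]
    )
    dm = DistanceMatrix(taxa, d, np.zeros((4, 4), dtype=bool))
    tree = nj_tree(dm)
    pd = patristic(tree)
    for i, a in enumerate(taxa):
        for j in range(i + 1, 4):
            assert pd[(a, taxa[j])] == pytest.approx(d[i, j]), (a, taxa[j])


@pytest.mark.parametrize("n", [5, 8, 12])
def test_nj_exact_on_random_additive_matrices(n):
    rng = random.Random(100 + n)
    for _ in range(5):
        true = random_binary_tree(n, rng)
        tree = nj_tree(dm_from_tree(true))
        assert robinson_foulds(tree, true) == 0


def test_nj_deterministic():
    rng = random.Random(7)
    dm = dm_from_tree(random_binary_tree(6, rng))
    s1 = nj_tree(dm).as_string(schema="newick")
    s2 = nj_tree(dm).as_string(schema="newick")
    assert s1 == s2


def test_concatenation_widths_and_padding(family_dataset):
    genomes = list(family_dataset["leaves"].values())[:4]
    blocks = build_gene_alignments(genomes)
    sm = concatenate_pcgs(blocks)
    assert sm.nchar == sum(b.nchar for b in blocks.values())
    assert [lbl for lbl, _, _ in sm.partitions] == list(blocks)
    # drop one gene from one taxon: padded with gaps
    partial = {g: b for g, b in blocks.items()}
    nd1 = partial["ND1"]
    partial["ND1"] = AlignmentBlock(nd1.taxa[:-1], nd1.rows[:-1])
    sm2 = concatenate_pcgs(partial)
    lbl, s, e = [p for p in sm2.partitions if p[0] == "ND1"][0]
    assert sm2.row(nd1.taxa[-1])[s - 1 : e] == "-" * (e - s + 1)


def test_bootstrap_determinism_and_bounds(family_supermatrix):
    t1 = bootstrap(family_supermatrix, replicates=10, seed=42)
    t2 = bootstrap(family_supermatrix, replicates=10, seed=42)
    s1 = [nd.label for nd in t1.preorder_node_iter() if nd.label]
    s2 = [nd.label for nd in t2.preorder_node_iter() if nd.label]
    assert s1 == s2
    assert all(0 <= int(x) <= 100 for x in s1)
    with pytest.raises(ValueError):
        bootstrap(family_supermatrix, replicates=0, seed=1)


def test_bootstrap_star_data_has_weak_support():
    rng = random.Random(12)
    rows = ["".join(rng.choice("ACGT") for _ in range(400)) for _ in range(6)]
    a = AlignmentBlock([f"s{i}" for i in range(6)], rows)
    t = bootstrap(a, replicates=30, seed=5, model="p")
    supports = [int(nd.label) for nd in t.preorder_node_iter() if nd.label]
    assert min(supports) < 100


def test_bootstrap_invariant_to_taxon_order(family_supermatrix):
    a = family_supermatrix
    order = list(range(len(a.taxa)))[::-1]
    b = AlignmentBlock([a.taxa[i] for i in order], [a.rows[i] for i in order],
                       list(a.partitions))

    def support_map(tree):
        from mitochar.phylo import bipartitions
        out = {}
        leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        for nd in tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None or not nd.label:
                continue
            below = frozenset(l.taxon.label for l in nd.leaf_iter())
            canon = frozenset(min((tuple(sorted(below)), tuple(sorted(leaves - below)))))
            out[canon] = nd.label
        return out

    m1 = support_map(bootstrap(a, replicates=15, seed=9))
    m2 = support_map(bootstrap(b, replicates=15, seed=9))
    assert set(m1) == set(m2)


def test_check_clades(family_dataset, family_supermatrix):
    tree = nj_tree(distance_matrix(family_supermatrix, "JC69"))
    omeimontis_group = {
        "Boulenophrys_sangzhiensis", "Boulenophrys_omeimontis", "Boulenophrys_spinata",
    }
    boettgeri_group = {
        "Boulenophrys_tuberogranulata", "Boulenophrys_jingganggensis",
        "Boulenophrys_boettgeri", "Boulenophrys_kuatunensis",
        "Boulenophrys_baishanzuensis",
    }
    res = check_clades(tree, [omeimontis_group, boettgeri_group,
                              {"Boulenophrys_spinata"}],
                       outgroup="Microhyla_fissipes")
    assert res == [True, True, True]
    with pytest.raises(KeyError):
        check_clades(tree, [{"nonexistent_taxon"}], outgroup="Microhyla_fissipes")
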