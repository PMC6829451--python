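"""Supermatrix construction, NJ correctness, RF distance, bootstrap."""

import dendropy
import numpy as np
import pytest

from mitocompare import concatenate, nj_tree, robinson_foulds
from mitocompare.phylo import (
    bootstrap_support,
    clade_support,
    k2p_matrix_from_array,
    tree_splits,
    write_nexus,
)
from mitocompare.synthetic import simulate_alignment


def test_concatenate_widths_and_padding():
    aln = {
        "cox1": {"t1": "ACGTAC", "t2": "ACGTAC", "t3": "ACGAAC"},
        "cob": {"t1": "GGGG", "t2": "GGGT"},  # t3 missing
    }
    sm = concatenate(aln)
    assert sm.width == 10
    # canonical gene order puts cob before cox1, so t3's missing cob
    # partition is gap-padded at the front
    assert sm.rows["t3"].startswith("----")
    assert ("t3", "cob") in sm.padded
    assert [p[0] for p in sm.partitions] == ["cob", "cox1"]
    assert sum(e - s for _, s, e in sm.partitions) == sm.width


def test_seventeen_partitions_canonical_order():
    taxa = {"x": "ACGT", "y": "ACGT", "z": "ACGA"}
    genes = ["atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3", "nad1",
             "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
             "rnl", "rns"]
    sm = concatenate({g: dict(taxa) for g in genes})
    assert len(sm.partitions) == 17
    assert [p[0] for p in sm.partitions][-2:] == ["rnl", "rns"]


def test_duplicate_taxon_rejected():
    with pytest.raises(ValueError):
        concatenate({"g": {"t1": "ACGT", "t2": "ACG"}})  # unequal rows


def test_nj_three_taxa_closed_form():
    taxa = ["a", "b", "c"]
    m = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(taxa, m)
    dists = {}
    pdm = tree.phylogenetic_distance_matrix()
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            dists[(t1.label, t2.label)] = pdm.distance(t1, t2)
    assert dists[("a", "b")] == pytest.approx(0.3)
    assert dists[("a", "c")] == pytest.approx(0.5)
    assert dists[("b", "c")] == pytest.approx(0.6)


def random_additive_tree(rng, ntaxa):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix (the additive-distance oracle)."""
    taxa = [f"t{i}" for i in range(ntaxa)]
    tree = dendropy.Tree()
    tree.taxon_namespace = dendropy.TaxonNamespace(taxa)
    nodes = []
    for label in taxa[:3]:
        leaf = dendropy.Node(edge_length=float(rng.uniform(0.05, 0.6)))
        leaf.taxon = tree.taxon_namespace.get_taxon(label)
        tree.seed_node.add_child(leaf)
        nodes.append(leaf)
    for label in taxa[3:]:
        edge = nodes[int(rng.integers(len(nodes)))]
        mid = dendropy.Node(edge_length=edge.edge.length * 0.5)
        parent = edge.parent_node
        parent.remove_child(edge)
        parent.add_child(mid)
        edge.edge.length *= 0.5
        mid.add_child(edge)
        leaf = dendropy.Node(edge_length=float(rng.uniform(0.05, 0.6)))
        leaf.taxon = tree.taxon_namespace.get_taxon(label)
        mid.add_child(leaf)
        nodes.extend([leaf, mid])
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((ntaxa, ntaxa))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                m[i, j] = pdm.distance(
                    tree.taxon_namespace.get_taxon(a),
                    tree.taxon_namespace.get_taxon(b),
                )
    return taxa, tree, m


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_nj_exact_on_additive_matrices(seed):
    rng = np.random.default_rng(seed)
    for _ in range(5):
        ntaxa = int(rng.integers(4, 10))
        taxa, true_tree, m = random_additive_tree(rng, ntaxa)
        est = nj_tree(taxa, m)
        assert robinson_foulds(est, true_tree) == 0
        # path lengths reproduce the input matrix exactly (additivity)
        pdm = est.phylogenetic_distance_matrix()
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    got = pdm.distance(est.taxon_namespace.get_taxon(a),
                                       est.taxon_namespace.get_taxon(b))
                    assert got == pytest.approx(m[i, j], abs=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(["a", "b"], np.zeros((2, 2)))
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = np.nan
    with pytest.raises(ValueError):
        nj_tree(["a", "b", "c"], m)


def test_rf_zero_on_self_and_two_on_alternative_quartets():
    t1 = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
    t2 = dendropy.Tree.get(data="((a,c),(b,d));", schema="newick")
    assert robinson_foulds(t1, t1) == 0
    assert robinson_foulds(t1, t2) == 2
    with pytest.raises(ValueError):
        t3 = dendropy.Tree.get(data="((a,b),(c,e));", schema="newick")
        robinson_foulds(t1, t3)


def test_bootstrap_three_taxa_always_supported():
    aln = {"g": {"a": "ACGTACGA" * 4, "b": "ACGTACGT" * 4,
                 "c": "ACGAACGT" * 4}}
    sm = concatenate(aln)
    _, support = bootstrap_support(sm, replicates=2, seed=0)
    assert support == {}  # 3 taxa: no non-trivial splits; unique topology


def test_bootstrap_deterministic_under_seed(pair):
    truth = pair[2]
    aln = simulate_alignment(truth["tree"], 2000, seed=21)
    sm = concatenate({"g": aln})
    _, s1 = bootstrap_support(sm, replicates=25, seed=5)
    _, s2 = bootstrap_support(sm, replicates=25, seed=5)
    assert s1 == s2


def test_sister_pair_recovered_with_high_support(pair):
    truth = pair[2]
    aln = simulate_alignment(truth["tree"], 10_000, seed=9)
    sm = concatenate({"g": aln})
    tree, support = bootstrap_support(sm, replicates=100, seed=9)
    sisters = set(truth["sister_pair"])
    assert frozenset(sisters) in tree_splits(tree)
    assert clade_support(support, sisters) >= 97.0


def test_trees_from_disjoint_halves_agree():
    rng_tree = "((a:0.05,b:0.06):0.2,(c:0.2,d:0.25):0.1,e:0.4);"
    aln = simulate_alignment(rng_tree, 20_000, seed=13)
    taxa = sorted(aln)
    half1 = {t: s[:10_000] for t, s in aln.items()}
    half2 = {t: s[10_000:] for t, s in aln.items()}
    trees = []
    for half in (half1, half2):
        sm = concatenate({"g": half})
        arr = sm.array()
        trees.append(nj_tree(sm.taxa, k2p_matrix_from_array(arr, sm.taxa)))
    assert robinson_foulds(trees[0], trees[1]) == 0


def test_nexus_export_roundtrips_dimensions(tmp_path):
    aln = {"cox1": {"t one": "ACGT", "t2": "ACGT", "t3": "ACGA"}}
    sm = concatenate(aln)
    out = tmp_path / "sm.nex"
    write_nexus(sm, out)
    text = out.read_text()
    assert "NTAX=3" in text and "NCHAR=4" in text
    assert "CHARSET cox1 = 1-4" in text
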