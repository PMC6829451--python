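"""Region partition conservation, overlaps, intergenic spans, decomposition."""

import numpy as np
import pytest

from mitocompare import expansion_decomposition, intergenic_summary, partition
from mitocompare.regions import CATEGORIES, RegionPartition

from conftest import feat, make_genome, random_annotated_genome


def test_single_cds_proportions():
    g = make_genome("A" * 100, [feat("x", "CDS", [(10, 40)])])
    p = partition(g)
    assert p.lengths["protein_coding"] == 30
    assert p.lengths["intergenic"] == 70
    assert p.proportions["protein_coding"] == pytest.approx(30.0)


def test_intron_bases_labeled_intronic():
    g = make_genome("A" * 100, [feat("x", "CDS", [(10, 40), (60, 90)])])
    p = partition(g)
    assert p.lengths["protein_coding"] == 60
    assert p.lengths["intronic"] == 20
    assert p.lengths["intergenic"] == 20


def test_overlap_detected_with_bruteforce_check():
    g = make_genome(
        "A" * 400,
        [feat("x", "CDS", [(0, 200)]), feat("y", "CDS", [(115, 300)])],
    )
    p = partition(g)
    assert p.overlaps == [("x", "y", 85)]
    # brute-force per-base intersection
    base = np.zeros(400, dtype=int)
    base[0:200] += 1
    base[115:300] += 1
    assert (base == 2).sum() == 85
    # overlapping bases counted once: conservation holds
    assert sum(p.lengths.values()) == 400
    assert p.lengths["protein_coding"] == 300


def test_circular_intergenic_span():
    g = make_genome("A" * 100, [feat("x", "CDS", [(30, 60)])])
    summary = intergenic_summary(partition(g))
    assert summary["count"] == 1
    assert summary["total"] == summary["max"] == 70


def test_intergenic_extrema():
    # spans of 37, 500 and 1791 bp between three genes on a circle
    sizes = [37, 500, 1791]
    pos = 0
    feats = []
    for i, gap in enumerate(sizes):
        pos += gap
        feats.append(feat(f"g{i}", "CDS", [(pos, pos + 90)]))
        pos += 90
    g = make_genome("A" * pos, feats, circular=False)
    s = intergenic_summary(partition(g))
    assert (s["min"], s["max"]) == (37, 1791)
    assert s["total"] == sum(sizes)


def test_decomposition_requires_unequal_sizes():
    p = partition(make_genome("A" * 100, [feat("x", "CDS", [(0, 30)])]))
    with pytest.raises(ValueError):
        expansion_decomposition(p, p)


def test_decomposition_toy_arithmetic():
    a = RegionPartition(
        genome_id="a", length=100,
        lengths={"protein_coding": 40, "intronic": 10, "rna": 0,
                 "intergenic": 50},
        proportions={},
    )
    b = RegionPartition(
        genome_id="b", length=150,
        lengths={"protein_coding": 30, "intronic": 70, "rna": 0,
                 "intergenic": 50},
        proportions={},
    )
    d = expansion_decomposition(a, b)
    assert d.size_difference == 50
    assert d.contributions["intronic"] == pytest.approx(120.0)
    assert d.contributions["protein_coding"] == pytest.approx(-20.0)
    assert d.contributions["intergenic"] == pytest.approx(0.0)


def test_unannotated_genome_warns_all_intergenic():
    with pytest.warns(UserWarning):
        p = partition(make_genome("ACGT" * 50))
    assert p.lengths["intergenic"] == 200


def test_conservation_on_random_genomes():
    """Category lengths always sum to the genome length, and the
    decomposition closes at exactly 100%, whatever the annotation."""
    rng = np.random.default_rng(42)
    parts = []
    for _ in range(40):
        g = random_annotated_genome(rng)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = partition(g)
        assert sum(p.lengths.values()) == len(g.sequence)
        assert sum(p.proportions.values()) == pytest.approx(100.0)
        parts.append(p)
    for p, q in zip(parts, parts[1:]):
        if p.length != q.length:
            d = expansion_decomposition(p, q)
            assert sum(d.contributions.values()) == pytest.approx(100.0)


def test_partition_invariant_under_feature_reordering(pair):
    a = pair[0]
    shuffled = make_genome(a.sequence, list(reversed(a.features)),
                           genome_id=a.id)
    p1, p2 = partition(a), partition(shuffled)
    assert p1.lengths == p2.lengths
    assert sorted(p1.overlaps) == sorted(p2.overlaps)


def test_pair_partition_matches_generator_bookkeeping(pair):
    a, b, truth = pair
    for g, key in ((a, "a"), (b, "b")):
        p = partition(g)
        assert p.lengths == truth["region_lengths"][key]
        assert set(p.lengths) == set(CATEGORIES)
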