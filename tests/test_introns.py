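"""Intron extraction, position classes, and gain/loss tallies."""

import pytest

from mitocompare import assign_pcls, extract_introns, gain_loss_table, rotate
from mitocompare._codon import revcomp
from mitocompare.introns import IntronRecord

from conftest import feat, make_genome


def test_intronless_genome_yields_nothing():
    g = make_genome("A" * 300, [feat("x", "CDS", [(0, 90)])])
    assert extract_introns(g) == []


def test_insertion_coordinate_is_upstream_exon_length():
    g = make_genome("A" * 400, [feat("x", "CDS", [(0, 100), (150, 300)])])
    (rec,) = extract_introns(g)
    assert rec.coordinate == 100
    assert rec.length == 50
    assert rec.host == "x"


def test_minus_strand_coordinate_against_bruteforce_scan():
    """On the minus strand the coordinate counts along the coding strand."""
    seq = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(400))
    exons = [(50, 140), (180, 300)]
    g = make_genome(seq, [feat("x", "CDS", exons, strand="-")])
    (rec,) = extract_introns(g)
    # brute force: walk the spliced coding sequence and find where the intron
    # falls by comparing prefixes of the coding strand
    coding = revcomp(seq[50:140] + seq[180:300])
    first_exon_transcribed = revcomp(seq[180:300])
    assert coding[: len(first_exon_transcribed)] == first_exon_transcribed
    assert rec.coordinate == len(first_exon_transcribed) == 120
    assert rec.sequence == revcomp(seq[140:180])


def test_same_coordinate_high_identity_shared():
    ia = [IntronRecord("cox1", "A", 222, "ACGT" * 50)]
    ib = [IntronRecord("cox1", "B", 222, "ACGT" * 49 + "ACGA")]
    (pcl,) = assign_pcls(ia, ib)
    assert pcl.shared and not pcl.low_similarity
    assert pcl.identity > 0.95


def test_same_coordinate_low_identity_flagged():
    ia = [IntronRecord("cox1", "A", 222, "ACGT" * 50)]
    ib = [IntronRecord("cox1", "B", 222, "TTAA" * 50)]
    (pcl,) = assign_pcls(ia, ib, identity_threshold=0.9)
    assert pcl.shared and pcl.low_similarity


def test_genome_specific_intron_is_unshared():
    ia = [IntronRecord("cox2", "A", 543, "ACGT" * 30)]
    pcls = assign_pcls(ia, [])
    assert len(pcls) == 1 and not pcls[0].shared
    assert pcls[0].coordinate == 543


def test_cox1_letters_from_exemplars_else_provisional():
    ia = [IntronRecord("cox1", "A", 222, "ACGT" * 30),
          IntronRecord("cox1", "A", 999, "ACGT" * 30)]
    pcls = assign_pcls(ia, [], cox1_exemplars={222: "K"})
    ids = {p.coordinate: p.pcl_id for p in pcls}
    assert ids[222] == "K"
    assert ids[999] == "cox1-p999"


def test_pair_intron_counts_and_pcl_structure(pair):
    a, b, truth = pair
    ia, ib = extract_introns(a), extract_introns(b)
    assert len(ia) == truth["intron_counts"]["a"] == 16
    assert len(ib) == truth["intron_counts"]["b"] == 24
    pcls = assign_pcls(ia, ib, cox1_exemplars=truth["cox1_exemplars"])
    # partition property: every intron in exactly one position class
    assert sum(len(p.members) for p in pcls) == len(ia) + len(ib)
    by_gene = {}
    for p in pcls:
        row = by_gene.setdefault(p.host, {"shared": 0, "a_only": 0,
                                          "b_only": 0})
        if p.shared:
            row["shared"] += 1
        elif p.n_a:
            row["a_only"] += 1
        else:
            row["b_only"] += 1
    for host, expected in truth["pcl_expected"].items():
        got = by_gene[host]
        assert got["shared"] == expected["shared"], host
        assert got["a_only"] == expected["a_only"], host
        assert got["b_only"] == expected["b_only"], host
    # shared classes planted at 97% identity clear the 0.70 default threshold
    assert all(not p.low_similarity for p in pcls if p.shared)


def test_gain_loss_fractions(pair):
    a, b, truth = pair
    pcls = assign_pcls(extract_introns(a), extract_introns(b))
    table = gain_loss_table(pcls)
    for host, expected in truth["pcl_expected"].items():
        assert table.loc[host, "fraction_non_homologous"] == pytest.approx(
            expected["fraction_non_homologous"]), host
    assert table.loc["cob", "fraction_non_homologous"] == pytest.approx(
        100 / 7)
    assert table.loc["rnl", "fraction_non_homologous"] == 100.0


def test_all_shared_gives_zero_fraction():
    ia = [IntronRecord("cob", "A", 10, "ACGT" * 30)]
    ib = [IntronRecord("cob", "B", 10, "ACGT" * 30)]
    table = gain_loss_table(assign_pcls(ia, ib))
    assert table.loc["cob", "fraction_non_homologous"] == 0.0


def test_coordinates_invariant_under_rotation(pair):
    a = pair[0]
    base = sorted((r.host, r.coordinate) for r in extract_introns(a))
    for offset in (1234, 40000):
        rot = rotate(a, offset)
        assert sorted((r.host, r.coordinate)
                      for r in extract_introns(rot)) == base


def test_inconsistent_exons_raise():
    g = make_genome(
        "A" * 300,
        [feat("bad", "CDS", [(0, 100), (150, 250)])],
    )
    # corrupt the intervals: overlapping exons on a non-wrapping feature are
    # rejected at construction time already
    with pytest.raises(ValueError):
        feat("bad2", "CDS", [(0, 100), (50, 250)])
    assert extract_introns(g)  # the clean version still works
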