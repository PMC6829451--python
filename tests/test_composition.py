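"""Base composition, skews, and codon usage under genetic code 4."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocompare import codon_usage, composition_stats, start_stop_table
from mitocompare._codon import GENETIC_CODE_4, STOP_CODONS_4, revcomp
from mitocompare.synthetic import BASE_PROBS

from conftest import feat, make_genome

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


@pytest.mark.parametrize(
    "seq, at_skew, gc_skew, gc",
    [
        ("ATAT", 0.0, 0.0, 0.0),
        ("GGGC", 0.0, 0.5, 100.0),
        ("AATT", 0.0, 0.0, 0.0),
        ("AAAT", 0.5, 0.0, 0.0),
        ("ACGT", 0.0, 0.0, 50.0),
    ],
)
def test_composition_examples(seq, at_skew, gc_skew, gc):
    with pytest.warns(UserWarning) if set(seq) <= {"A", "T"} or set(seq) <= {
        "G", "C"
    } else _nullcontext():
        s = composition_stats(seq)
    assert s.at_skew == pytest.approx(at_skew)
    assert s.gc_skew == pytest.approx(gc_skew)
    assert s.gc_content == pytest.approx(gc)


def _nullcontext():
    import contextlib

    return contextlib.nullcontext()


def test_empty_and_all_n_rejected():
    with pytest.raises(ValueError):
        composition_stats("")
    with pytest.raises(ValueError):
        composition_stats("NNNN")


@settings(max_examples=60, deadline=None)
@given(dna)
def test_skew_antisymmetry_under_reverse_complement(seq):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s, r = composition_stats(seq), composition_stats(revcomp(seq))
    assert r.at_skew == pytest.approx(-s.at_skew)
    assert r.gc_skew == pytest.approx(-s.gc_skew)
    assert r.gc_content == pytest.approx(s.gc_content)
    assert s.gc_content + s.at_content == pytest.approx(100.0)


def test_codon_usage_single_cds():
    g = make_genome("TTATTA" + "A" * 24, [feat("x", "CDS", [(0, 6)])])
    t = codon_usage(g, ["x"])
    assert t.counts["TTA"] == 2
    assert t.frequencies["TTA"] == pytest.approx(1.0)


def test_codon_usage_start_stop_and_counts():
    g = make_genome("ATGAAATAA" + "C" * 21, [feat("x", "CDS", [(0, 9)])])
    t = codon_usage(g, ["x"])
    assert t.start_stop["x"] == ("ATG", "TAA")
    assert {c: n for c, n in t.counts.items() if n} == {
        "ATG": 1, "AAA": 1, "TAA": 1
    }


def test_codon_frequencies_invariant_under_gene_order(pair):
    a = pair[0]
    genes = sorted(a.core_cds())
    t1 = codon_usage(a, genes)
    t2 = codon_usage(a, genes[::-1])
    assert t1.counts == t2.counts


def test_top_codons_match_sampling_distribution(pair):
    """Top-ranked codons in the AT-rich pooled table equal the top codons of
    the generator's codon distribution (stop codons excluded)."""
    a = pair[0]
    observed = codon_usage(a).top_codons(6)

    def prob(codon):
        return float(np.prod([BASE_PROBS[b] for b in codon]))

    ranked = sorted(
        (c for c in GENETIC_CODE_4 if c not in STOP_CODONS_4),
        key=lambda c: -prob(c),
    )
    # neighbouring ranks differ by less than sampling noise at ~5k codons,
    # so require the observed top codons to come from the distribution's
    # top tier rather than an exact rank-by-rank match
    assert set(observed) <= set(ranked[:7])
    assert observed[0] in ranked[:4]
    assert all(set(c) <= {"A", "T"} for c in observed)


def test_nonstandard_start_stop_flagged(pair):
    table = start_stop_table(pair[0])
    assert table.loc["cox1", "start_codon"] == "TTG"
    assert bool(table.loc["cox1", "nonstandard_start"])
    assert table.loc["cob", "stop_codon"] == "TAG"
    assert bool(table.loc["cob", "nonstandard_stop"])
    standard = table.drop(["cox1", "cob"])
    assert not standard["nonstandard_start"].any()
    assert not standard["nonstandard_stop"].any()


def test_tga_is_tryptophan_not_stop():
    assert GENETIC_CODE_4["TGA"] == "W"
    assert "TGA" not in STOP_CODONS_4


def test_short_cds_rejected_in_start_stop_table():
    g = make_genome("ATGAA" + "C" * 25, [feat("x", "CDS", [(0, 5)])])
    with pytest.raises(ValueError):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_stop_table(g, ["x"])
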