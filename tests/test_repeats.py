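"""Repeat detectors against brute-force scans and planted ground truth."""

import numpy as np
import pytest

from mitocompare import exact_repeats, similarity_hits, tandem_repeats
from mitocompare._codon import complement, revcomp
from mitocompare.repeats import tandem_coverage_percent


def _rand(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=list(p)))


def bruteforce_exact(seq, min_length):
    """Independent all-diagonals scan for maximal exact repeated pairs."""
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    transforms = {
        "forward": seq,
        "reverse": seq[::-1],
        "complemented": complement(seq),
        "palindromic": revcomp(seq),
    }
    hits = set()
    for orient, tstr in transforms.items():
        t = np.frombuffer(tstr.encode(), dtype=np.uint8)
        for d in range(-(n - min_length), n - min_length + 1):
            if orient in ("forward", "complemented") and d == 0:
                continue
            i0, k0 = max(0, d), max(0, -d)
            ln = n - abs(d)
            if ln < min_length:
                continue
            m = s[i0 : i0 + ln] == t[k0 : k0 + ln]
            padded = np.concatenate(([0], m.astype(np.int8), [0]))
            step = np.diff(padded)
            for rs, re_ in zip(np.flatnonzero(step == 1),
                               np.flatnonzero(step == -1)):
                length = int(re_ - rs)
                if length < min_length:
                    continue
                i, k = i0 + int(rs), k0 + int(rs)
                if orient in ("forward", "complemented"):
                    j = k
                else:
                    j = n - k - length
                loc1, loc2 = (i, i + length), (j, j + length)
                if loc1 == loc2:
                    continue
                if loc2 < loc1:
                    loc1, loc2 = loc2, loc1
                hits.add((loc1, loc2, orient))
    return hits


@pytest.mark.parametrize("seed", range(6))
def test_exact_repeats_equal_bruteforce_random(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(150, 900))
    seq = _rand(rng, n)
    got = {(h.locus1, h.locus2, h.orientation)
           for h in exact_repeats(seq, min_length=8)}
    assert got == bruteforce_exact(seq, 8)


def test_exact_repeats_planted_forward():
    rng = np.random.default_rng(7)
    left, seg, mid, right = (_rand(rng, 300), _rand(rng, 50),
                             _rand(rng, 200), _rand(rng, 250))
    seq = left + "G" + seg + "C" + mid + "C" + seg + "G" + right
    hits = [h for h in exact_repeats(seq, 30) if h.orientation == "forward"]
    target = (301, 351)
    assert any(h.locus1 == target and h.length == 50 for h in hits)


def test_exact_repeats_planted_palindromic():
    rng = np.random.default_rng(8)
    left, seg, mid, right = (_rand(rng, 200), _rand(rng, 40),
                             _rand(rng, 150), _rand(rng, 200))
    seq = left + "G" + seg + mid + revcomp(seg) + "G" + right
    hits = [h for h in exact_repeats(seq, 30)
            if h.orientation == "palindromic"]
    # chance complementarity at the inner junctions can extend the maximal
    # match beyond the planted segment, so assert containment
    assert any(
        h.locus1[0] <= 201 and h.locus1[1] >= 241 and h.length >= 40
        for h in hits
    )


def test_random_sequence_has_no_long_repeats():
    rng = np.random.default_rng(9)
    seq = _rand(rng, 1000)
    assert exact_repeats(seq, min_length=20) == []  # probabilistic, ~4^-20


def test_min_length_floor():
    with pytest.raises(ValueError):
        exact_repeats("ACGT" * 100, min_length=4)


def test_orientation_maps_under_genome_reversal():
    rng = np.random.default_rng(10)
    seq = (_rand(rng, 120) + "G" + _rand(rng, 40) + "C" + _rand(rng, 90))
    seg = seq[121:161]
    seq = seq + "A" + seg + "T" + _rand(rng, 80)
    fwd = {(h.locus1, h.locus2) for h in exact_repeats(seq, 25)
           if h.orientation == "forward"}
    n = len(seq)
    rev = {(h.locus1, h.locus2) for h in exact_repeats(seq[::-1], 25)
           if h.orientation == "forward"}
    mirrored = {
        tuple(sorted(((n - b, n - a), (n - d, n - c))))
        for (a, b), (c, d) in fwd
    }
    assert rev == mirrored


def test_tandem_toy_example():
    (t,) = tandem_repeats("TTGG" + "ACGTACGTACGT" + "TTCC", min_unit=4,
                          min_copies=2)
    assert t.period == 4
    assert t.copies == pytest.approx(3.0)
    assert t.consensus == "ACGT"


def test_tandem_planted_recovery(pair):
    a, b, truth = pair
    detected = tandem_repeats(b.sequence)
    for plant in truth["tandems"]:
        if plant["genome"] != "b":
            continue
        match = [t for t in detected if t.period == plant["unit"]
                 and t.locus[0] <= plant["locus"][0]
                 and t.locus[1] >= plant["locus"][1] - plant["unit"]]
        assert match, plant
        assert match[0].copies == pytest.approx(plant["copies"], abs=1.0)
    high = max(t.copies for t in detected)
    assert high == pytest.approx(13, abs=1.0)


def test_tandem_coverage_bounds_and_monotonicity(pair):
    b = pair[1].sequence
    prev = 101.0
    for unit in (11, 15, 25):
        reps = tandem_repeats(b, min_unit=unit)
        cov = tandem_coverage_percent(reps, len(b))
        assert 0.0 <= cov <= 100.0
        assert cov <= prev + 1e-9
        prev = cov


def test_similarity_disjoint_random_has_no_hits():
    rng = np.random.default_rng(11)
    q, s = _rand(rng, 5000), _rand(rng, 5000)
    assert similarity_hits([q], [s]) == []


def test_similarity_recovers_planted_duplicate(pair):
    b, truth = pair[1], pair[2]
    hits = similarity_hits([b.sequence], [b.sequence])
    (l1, l2) = truth["duplicate"]["loci"]
    match = [
        h for h in hits
        if h.orientation == "forward"
        and h.locus1[0] <= l1[0] + 5 and h.locus1[1] >= l1[1] - 5
        and h.locus2[0] <= l2[0] + 5 and h.locus2[1] >= l2[1] - 5
    ]
    assert match
    hit = match[0]
    assert hit.length >= 0.95 * truth["duplicate"]["length"]
    assert hit.identity == pytest.approx(
        100 * truth["duplicate"]["identity"], abs=2.0)
    assert hit.evalue < 1e-10


def test_similarity_finds_numt_style_fragment(pair):
    """A mitochondrial fragment inserted into a synthetic nuclear contig at
    ~95% identity is recovered nearly full length."""
    rng = np.random.default_rng(12)
    mito = pair[0].sequence
    frag = mito[10_000:12_000]
    decayed = list(frag)
    for i in rng.choice(len(frag), size=100, replace=False):
        decayed[i] = "ACGT"[rng.integers(4)]
    contig = _rand(rng, 4000) + "".join(decayed) + _rand(rng, 4000)
    hits = similarity_hits([mito], [contig], min_identity=80.0)
    spanning = [h for h in hits
                if h.locus2[0] <= 4100 and h.locus2[1] >= 4000 + 0.9 * 2000]
    assert spanning
    assert spanning[0].length >= 0.9 * 2000
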