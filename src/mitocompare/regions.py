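"""Per-base decomposition of a mitogenome into functional region categories.

Every base is assigned exactly one of {protein_coding, rna, intronic,
intergenic} with priority protein_coding > rna > intronic > intergenic, so the
category totals always sum to the genome length even when genes overlap.
Hypothetical ORFs nested inside introns count as intronic (they travel with
the intron); standalone ORFs count as protein coding.

The same partition supports the between-genome size-expansion decomposition:
for genomes a and b differing in size, each category's contribution is

    contribution(c) = (len_c(b) - len_c(a)) / (size(b) - size(a)) * 100

signed percentages that sum to exactly 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotatedMitogenome, GeneFeature

CATEGORIES = ("protein_coding", "intronic", "rna", "intergenic")

_INTERGENIC, _INTRONIC, _RNA, _CODING = 0, 1, 2, 3
_CODE_TO_CATEGORY = {
    _INTERGENIC: "intergenic", _INTRONIC: "intronic",
    _RNA: "rna", _CODING: "protein_coding",
}


@dataclass
class IntergenicSpan:
    left: str   # name of the feature 5' of the span (forward-strand sense)
    right: str
    start: int
    end: int    # may wrap: end < start means the span crosses the origin
    length: int


@dataclass
class RegionPartition:
    genome_id: str
    length: int
    lengths: dict[str, int]
    proportions: dict[str, float]  # percent of genome
    overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    intergenic_spans: list[IntergenicSpan] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "length_bp": [self.lengths[c] for c in CATEGORIES],
                "percent": [round(self.proportions[c], 2) for c in CATEGORIES],
            }
        ).set_index("category")


def intron_intervals(genome: AnnotatedMitogenome) -> list[tuple[int, int]]:
    """Genomic intervals occupied by introns (gaps of multi-exon features plus
    explicit intron features)."""
    n = len(genome.sequence)
    spans: list[tuple[int, int]] = []
    for f in genome.features:
        if f.kind == "intron":
            spans.extend(f.intervals)
        elif f.kind in ("CDS", "rRNA", "tRNA", "ORF") and len(f.intervals) > 1:
            for (s1, e1), (s2, e2) in zip(f.intervals, f.intervals[1:]):
                if e1 <= s2:
                    spans.append((e1, s2))
                elif f.wraps_origin:  # gap crosses the origin
                    spans.extend([(e1, n), (0, s2)])
    return spans


def nested_orfs(genome: AnnotatedMitogenome) -> set[str]:
    """Names of ORF features fully contained inside an intron."""
    introns = intron_intervals(genome)
    nested = set()
    for f in genome.features:
        if f.kind != "ORF":
            continue
        if all(
            any(s >= is_ and e <= ie for is_, ie in introns)
            for s, e in f.intervals
        ):
            nested.add(f.name)
    return nested


def partition(genome: AnnotatedMitogenome) -> RegionPartition:
    """Label every base of the genome with one region category."""
    n = len(genome.sequence)
    labels = np.zeros(n, dtype=np.int8)  # intergenic
    nested = nested_orfs(genome)

    for s, e in intron_intervals(genome):
        labels[s:e] = _INTRONIC
    for f in genome.features:
        if f.kind == "ORF" and f.name in nested:
            continue  # intronic ORFs stay intronic
        target = {"CDS": _CODING, "ORF": _CODING, "tRNA": _RNA,
                  "rRNA": _RNA}.get(f.kind)
        if target is None:
            continue
        if target == _RNA:
            for s, e in f.intervals:
                np.maximum.at(labels, np.arange(s, e), _RNA)
        else:
            for s, e in f.intervals:
                labels[s:e] = _CODING

    if not genome.features:
        warnings.warn(f"genome {genome.id} has no annotation; "
                      "everything is intergenic")

    lengths = {
        _CODE_TO_CATEGORY[code]: int((labels == code).sum())
        for code in _CODE_TO_CATEGORY
    }
    proportions = {c: 100.0 * v / n for c, v in lengths.items()}
    return RegionPartition(
        genome_id=genome.id, length=n, lengths=lengths, proportions=proportions,
        overlaps=_gene_overlaps(genome, nested),
        intergenic_spans=_intergenic_spans(genome, labels, nested),
    )


def _exon_set(f: GeneFeature) -> list[tuple[int, int]]:
    return list(f.intervals)


def _gene_overlaps(
    genome: AnnotatedMitogenome, nested: set[str]
) -> list[tuple[str, str, int]]:
    feats = [
        f for f in genome.features_of_kind("CDS", "ORF", "tRNA", "rRNA")
        if f.name not in nested
    ]
    out = []
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            bp = 0
            for s1, e1 in a.intervals:
                for s2, e2 in b.intervals:
                    bp += max(0, min(e1, e2) - max(s1, s2))
            if bp > 0:
                out.append((a.name, b.name, bp))
    return out


def _intergenic_spans(
    genome: AnnotatedMitogenome, labels: np.ndarray, nested: set[str]
) -> list[IntergenicSpan]:
    n = len(labels)
    is_inter = labels == _INTERGENIC
    if is_inter.all():
        return []
    # runs of intergenic bases (linear scan; the wrap run is merged below)
    padded = np.concatenate(([0], is_inter.astype(np.int8), [0]))
    step = np.diff(padded)
    runs = [
        (int(s), int(e))
        for s, e in zip(np.flatnonzero(step == 1), np.flatnonzero(step == -1))
    ]
    # merge the wrap-around run on circular genomes
    wrapped: list[tuple[int, int]] = []
    if genome.circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1]
        wrapped.append((last[0], first[1]))  # end < start encodes the wrap
    elif genome.circular and runs and runs[0][0] == 0 and runs[0][1] == n:
        pass
    feats = [
        f for f in genome.features_of_kind("CDS", "ORF", "tRNA", "rRNA")
        if f.name not in nested
    ]

    def flanks(start: int, end: int) -> tuple[str, str]:
        left = right = ""
        best_l = -1
        best_r = 2 * n
        for f in feats:
            fe = f.end
            fs = f.start
            le = fe if fe <= start else fe - n  # allow circular left flank
            if le <= start and le > best_l:
                best_l, left = le, f.name
            rs = fs if fs >= end else fs + n
            if rs >= end and rs < best_r:
                best_r, right = rs, f.name
        return left, right

    spans = []
    for s, e in runs:
        l, r = flanks(s, e)
        spans.append(IntergenicSpan(left=l, right=r, start=s, end=e,
                                    length=e - s))
    for s, e in wrapped:
        l, r = flanks(s, e + n)
        spans.append(IntergenicSpan(left=l, right=r, start=s, end=e,
                                    length=(n - s) + e))
    return spans


def intergenic_summary(part: RegionPartition) -> dict:
    """Total/min/max intergenic span lengths and the longest span's flanks."""
    spans = part.intergenic_spans
    if not spans:
        return {"total": 0, "count": 0, "min": 0, "max": 0,
                "longest_flanks": ("", "")}
    longest = max(spans, key=lambda s: s.length)
    return {
        "total": sum(s.length for s in spans),
        "count": len(spans),
        "min": min(s.length for s in spans),
        "max": longest.length,
        "longest_flanks": (longest.left, longest.right),
    }


@dataclass(frozen=True)
class ExpansionDecomposition:
    size_difference: int  # bp, signed (b - a)
    contributions: dict[str, float]  # percent of the size difference, signed

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(CATEGORIES),
             "contribution_percent": [round(self.contributions[c], 2)
                                      for c in CATEGORIES]}
        ).set_index("category")


def expansion_decomposition(
    a: RegionPartition, b: RegionPartition
) -> ExpansionDecomposition:
    """Attribute the size difference between two genomes to region categories."""
    diff = b.length - a.length
    if diff == 0:
        raise ValueError("genomes have equal size; decomposition undefined")
    contributions = {
        c: 100.0 * (b.lengths[c] - a.lengths[c]) / diff for c in CATEGORIES
    }
    return ExpansionDecomposition(size_difference=diff,
                                  contributions=contributions)
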