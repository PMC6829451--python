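"""Base composition, strand skews, and codon usage under genetic code 4.

Strand asymmetry follows the usual conventions

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the forward strand; a zero denominator yields a skew of 0 (with a
warning) so whole-genome tables stay total. N bases are excluded from every
denominator.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._codon import GENETIC_CODE_4, STOP_CODONS_4
from .io import CORE_GENES, AnnotatedMitogenome, coding_sequence


@dataclass(frozen=True)
class CompositionStats:
    length: int
    a: int
    c: int
    g: int
    t: int
    gc_content: float  # percent
    at_content: float  # percent
    at_skew: float
    gc_skew: float

    def as_row(self) -> dict:
        return {
            "length": self.length, "A": self.a, "C": self.c, "G": self.g,
            "T": self.t, "gc_content": round(self.gc_content, 2),
            "at_content": round(self.at_content, 2),
            "at_skew": round(self.at_skew, 2), "gc_skew": round(self.gc_skew, 2),
        }


def composition_stats(seq: str) -> CompositionStats:
    """Counts, GC/AT content (percent of non-N bases) and both strand skews."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = Counter(seq)
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    acgt = a + c + g + t
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    at_skew = _skew(a - t, a + t, "AT")
    gc_skew = _skew(g - c, g + c, "GC")
    return CompositionStats(
        length=len(seq), a=a, c=c, g=g, t=t,
        gc_content=100.0 * (g + c) / acgt,
        at_content=100.0 * (a + t) / acgt,
        at_skew=at_skew, gc_skew=gc_skew,
    )


def _skew(num: int, den: int, label: str) -> float:
    if den == 0:
        warnings.warn(f"{label} skew denominator is 0; reporting skew 0",
                      stacklevel=3)
        return 0.0
    return num / den


@dataclass
class CodonUsageTable:
    """Pooled codon counts/frequencies plus per-gene start/stop codons."""

    counts: dict[str, int]
    total: int
    start_stop: dict[str, tuple[str, str]] = field(default_factory=dict)
    per_gene_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def frequencies(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / self.total for c, n in self.counts.items()}

    def amino_acid(self, codon: str) -> str:
        return GENETIC_CODE_4.get(codon, "*" if codon in STOP_CODONS_4 else "X")

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "amino_acid": self.amino_acid(c), "count": n,
             "frequency": n / self.total if self.total else 0.0}
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)

    def top_codons(self, k: int = 6) -> list[str]:
        return [c for c, _ in
                sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]


def codon_usage(
    genome: AnnotatedMitogenome,
    genes: list[str] | None = None,
) -> CodonUsageTable:
    """Codon usage over the selected CDS set (core genes by default).

    Codons are read in frame from each spliced coding sequence; trailing
    partial codons are dropped, and codons containing N are skipped.
    """
    if genes is None:
        genes = [g for g in CORE_GENES if g in genome.core_cds()]
    resolved: list[str] = []
    for g in genes:
        try:
            genome.get_cds(g)
        except KeyError:
            continue
        resolved.append(g)
    if not resolved:
        raise ValueError(f"genome {genome.id}: no resolvable CDS among {genes}")

    pooled: Counter[str] = Counter()
    per_gene: dict[str, dict[str, int]] = {}
    start_stop: dict[str, tuple[str, str]] = {}
    for g in resolved:
        cds = coding_sequence(genome, g)
        codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        codons = [c for c in codons if "N" not in c]
        gene_counts = Counter(codons)
        per_gene[g] = dict(gene_counts)
        pooled.update(gene_counts)
        if len(codons) >= 2:
            start_stop[g] = (codons[0], codons[-1])
    counts = {c: pooled.get(c, 0)
              for c in sorted(GENETIC_CODE_4) + sorted(STOP_CODONS_4)}
    return CodonUsageTable(
        counts=counts, total=sum(counts.values()),
        start_stop=start_stop, per_gene_counts=per_gene,
    )


def start_stop_table(
    genome: AnnotatedMitogenome, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene start/stop codons with flags for non-ATG starts, non-TAA stops."""
    if genes is None:
        genes = [g for g in CORE_GENES if g in genome.core_cds()]
    rows = []
    for g in genes:
        cds = coding_sequence(genome, g)
        if len(cds) < 6:
            raise ValueError(f"gene {g}: CDS shorter than 6 nt")
        start = cds[:3]
        ncod = len(cds) // 3
        stop = cds[3 * (ncod - 1) : 3 * ncod]
        rows.append({
            "gene": g, "start_codon": start, "stop_codon": stop,
            "nonstandard_start": start != "ATG",
            "nonstandard_stop": stop != "TAA",
        })
    return pd.DataFrame(rows).set_index("gene")
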