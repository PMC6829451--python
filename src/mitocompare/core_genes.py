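"""Per-gene divergence between two mitogenomes: K2P distance and NG86 Ka/Ks.

Kimura two-parameter distance
-----------------------------
With P and Q the transition and transversion proportions over compared
(gap/N-free) sites,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Nei-Gojobori (1986) Ka/Ks under genetic code 4
----------------------------------------------
Synonymous/nonsynonymous *sites* per codon are the expected fractions of the
three possible changes at each position that are synonymous (changes creating
a stop codon count as nonsynonymous, so sites always sum to 3 per codon);
*differences* between two codons are averaged with equal weight over the
minimal mutational pathways, skipping pathways that pass through a stop
codon. Both proportions receive the Jukes-Cantor correction

    d = -3/4 * ln(1 - 4p/3).

Ka/Ks is reported as None (NA) when Ks = 0; proportions >= 3/4 raise a
saturation error rather than returning a complex value.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log, sqrt

import pandas as pd
from Bio import Align

from ._codon import (
    BASES,
    GENETIC_CODE_4,
    STOP_CODONS_4,
    is_transition,
)
from .composition import composition_stats
from .io import CORE_GENES, AnnotatedMitogenome, coding_sequence


class SaturationError(ValueError):
    """Observed divergence too high for the distance correction."""


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


def transition_transversion_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(transitions, transversions, compared sites) with pairwise deletion of
    any column containing a gap or ambiguous base."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    ts = tv = n = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in BASES or y not in BASES:
            continue
        n += 1
        if x == y:
            continue
        if is_transition(x, y):
            ts += 1
        else:
            tv += 1
    return ts, tv, n


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences."""
    ts, tv, n = transition_transversion_counts(seq_a, seq_b)
    if n == 0:
        raise ValueError("no comparable (ungapped) sites")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={p:.3f}, Q={q:.3f} (saturated)"
        )
    return -0.5 * log(w1 * sqrt(w2))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites (0..3) in one sense codon.

    At each position, the fraction of the three possible point changes that
    preserve the amino acid; changes to a stop codon are nonsynonymous.
    """
    if codon in STOP_CODONS_4:
        raise ValueError(f"{codon} is a stop codon")
    aa = GENETIC_CODE_4[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE_4.get(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged with equal weight over minimal mutational pathways that avoid
    stop-codon intermediates.

    If every pathway passes through a stop codon (possible only for
    multi-step changes), all pathways are used as a fallback so the pair
    still contributes its full number of differences.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        cur = codon_a
        syn = non = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS_4 and nxt != codon_b:
                if not allow_stops:
                    return None
                non += 1.0  # stop intermediate: count as nonsynonymous step
            elif GENETIC_CODE_4.get(nxt, "*") == GENETIC_CODE_4.get(cur, "*"):
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        return syn, non

    results = [r for order in permutations(diff_pos)
               if (r := walk(tuple(order), allow_stops=False)) is not None]
    if not results:
        results = [walk(tuple(order), allow_stops=True)
                   for order in permutations(diff_pos)]
    syn = sum(r[0] for r in results) / len(results)
    non = sum(r[1] for r in results) / len(results)
    return syn, non


def _jukes_cantor(p: float, what: str) -> float:
    if p >= 0.75:
        raise SaturationError(f"{what} proportion {p:.3f} >= 0.75 (saturated)")
    if p == 0.0:
        return 0.0
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ka_ks: float | None  # None when Ks = 0
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons: int


def ka_ks(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks between two in-frame, equal-length coding sequences.

    Codon pairs containing gaps, Ns, or stop codons are skipped. Site counts
    are averaged over the two sequences.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences must be aligned to equal length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    usable = len(cds_a) - len(cds_a) % 3
    s_sites = n_sites = s_diff = n_diff = 0.0
    ncod = 0
    for i in range(0, usable, 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if ca not in GENETIC_CODE_4 or cb not in GENETIC_CODE_4:
            continue  # gap, N, or stop codon: excluded
        sa, sb = synonymous_site_fraction(ca), synonymous_site_fraction(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += 3.0 - (sa + sb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        s_diff += sd
        n_diff += nd
        ncod += 1
    if ncod == 0:
        raise ValueError("no comparable codons")
    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps, "synonymous")
    ka = _jukes_cantor(pn, "nonsynonymous")
    return KaKsResult(
        ka=ka, ks=ks, ka_ks=(ka / ks if ks > 0 else None),
        syn_sites=s_sites, nonsyn_sites=n_sites,
        syn_diffs=s_diff, nonsyn_diffs=n_diff, codons=ncod,
    )


# ---------------------------------------------------------------------------
# Alignment helpers and the per-gene table
# ---------------------------------------------------------------------------


def _nuc_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global nucleotide alignment (match +1 / mismatch -1 / gap -2)."""
    aln = _nuc_aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the global alignment of two sequences."""
    a, b = align_pair(seq_a, seq_b)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a) if a else 0.0


def codon_aware_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Align two in-frame CDS at the codon level via their translations.

    The protein global alignment (match +2 / mismatch -1 / gap open -6,
    extend -1) is back-mapped onto codons, producing equal-length nucleotide
    strings with '---' gaps that preserve the reading frame.
    """
    from ._codon import translate_4

    prot_a = translate_4(cds_a).rstrip("*")
    prot_b = translate_4(cds_b).rstrip("*")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a, prot_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in zip(ga, gb):
        if x == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if y == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


def amino_acid_differences(cds_a: str, cds_b: str) -> int:
    """Count of differing residues in the codon-aware protein alignment
    (gapped columns included)."""
    from ._codon import translate_4

    a, b = codon_aware_align(cds_a, cds_b)
    pa, pb = translate_4(a.replace("---", "XXX")), translate_4(b.replace("---", "XXX"))
    return sum(1 for x, y in zip(pa, pb) if x != y)


def core_gene_table(
    a: AnnotatedMitogenome, b: AnnotatedMitogenome
) -> pd.DataFrame:
    """Length, composition, K2P, Ka, Ks and Ka/Ks for every shared core gene.

    Equal-length genes are compared position-wise; unequal genes are globally
    aligned before K2P and codon-aware aligned before Ka/Ks.
    """
    shared = [g for g in CORE_GENES if g in a.core_cds() and g in b.core_cds()]
    if not shared:
        raise ValueError("no shared core genes between the two genomes")
    rows = []
    for gene in shared:
        ca, cb = coding_sequence(a, gene), coding_sequence(b, gene)
        sa, sb = composition_stats(ca), composition_stats(cb)
        if len(ca) == len(cb):
            k2p = k2p_distance(ca, cb)
        else:
            k2p = k2p_distance(*align_pair(ca, cb))
        aligned_a, aligned_b = (
            (ca, cb) if len(ca) == len(cb) else codon_aware_align(ca, cb)
        )
        kk = ka_ks(aligned_a, aligned_b)
        rows.append({
            "gene": gene,
            "length_a": len(ca), "length_b": len(cb),
            "gc_a": sa.gc_content, "gc_b": sb.gc_content,
            "at_skew_a": sa.at_skew, "at_skew_b": sb.at_skew,
            "gc_skew_a": sa.gc_skew, "gc_skew_b": sb.gc_skew,
            "k2p": k2p, "ka": kk.ka, "ks": kk.ks, "ka_ks": kk.ka_ks,
        })
    return pd.DataFrame(rows).set_index("gene")
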