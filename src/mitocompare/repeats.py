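"""Repeat detection in mitogenomes: exact, tandem, and interspersed.

Three detectors cover the classical repeat inventory of organelle genomes:

* :func:`exact_repeats` — all maximal exact repeated pairs in the four
  orientations (forward, reverse, complemented, palindromic = reverse
  complemented). "Maximal" means the match cannot be extended on either side.
* :func:`tandem_repeats` — loci where a unit of >= ``min_unit`` bp repeats
  consecutively, tolerating up to 20% mismatching positions between adjacent
  copies. Detection anchors on an exact periodic stretch, so heavily decayed
  arrays below that exactness are not reported.
* :func:`similarity_hits` — seeded (11-mer) local alignments between two
  sequence sets scored +1/-2 with gap penalty -2, filtered by a
  Karlin-Altschul E-value (database length = total subject length). Running a
  genome against itself with the identical-locus hits removed reproduces the
  classic self-BLASTn interspersed-repeat scan; running a mitogenome against
  nuclear contigs finds NUMT-style transferred fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from ._codon import complement, revcomp

ORIENTATIONS = ("forward", "reverse", "complemented", "palindromic")

# Karlin-Altschul parameters for the +1/-2 DNA scoring system at uniform
# base composition (lambda solves sum p_i p_j exp(lambda * s_ij) = 1).
KA_LAMBDA = 1.3328
KA_K = 0.621


@dataclass(frozen=True)
class RepeatHit:
    locus1: tuple[int, int]
    locus2: tuple[int, int]
    orientation: str
    length: int
    identity: float  # percent
    query_index: int = 0
    subject_index: int = 0
    score: float | None = None
    evalue: float | None = None


@dataclass(frozen=True)
class TandemRepeat:
    locus: tuple[int, int]
    period: int
    copies: float
    consensus: str

    @property
    def length(self) -> int:
        return self.locus[1] - self.locus[0]


# ---------------------------------------------------------------------------
# Maximal exact repeats
# ---------------------------------------------------------------------------


def _maximal_matches(s: str, t: str, min_length: int,
                     skip_same_index: bool) -> set[tuple[int, int, int]]:
    """All maximal (i, k, length>=min_length) with s[i:i+l] == t[k:k+l].

    Seeded on exact ``min_length``-mers and extended to maximality; the
    ``skip_same_index`` flag drops the trivial i == k diagonal (self-match
    when t is s or a position-preserving transform of it).
    """
    L = min_length
    index: dict[str, list[int]] = {}
    for k in range(len(t) - L + 1):
        index.setdefault(t[k : k + L], []).append(k)
    out: set[tuple[int, int, int]] = set()
    ns, nt = len(s), len(t)
    for i in range(ns - L + 1):
        word = s[i : i + L]
        for k in index.get(word, ()):  # noqa: B020
            if skip_same_index and i == k:
                continue
            # extend left
            a, b = i, k
            while a > 0 and b > 0 and s[a - 1] == t[b - 1]:
                a -= 1
                b -= 1
            if skip_same_index and a == b:
                continue
            # extend right
            ea, eb = i + L, k + L
            while ea < ns and eb < nt and s[ea] == t[eb]:
                ea += 1
                eb += 1
            out.add((a, b, ea - a))
    return out


def exact_repeats(seq: str, min_length: int = 30,
                  orientations: tuple[str, ...] = ORIENTATIONS) -> list[RepeatHit]:
    """All maximal exact repeated pairs of each orientation in one genome."""
    if min_length < 8:
        raise ValueError("min_length must be >= 8")
    seq = seq.upper()
    n = len(seq)
    hits: set[tuple[tuple[int, int], tuple[int, int], str]] = set()
    transforms = {
        "forward": seq,
        "reverse": seq[::-1],
        "complemented": complement(seq),
        "palindromic": revcomp(seq),
    }
    for orient in orientations:
        t = transforms[orient]
        same_index = orient in ("forward", "complemented")
        for i, k, length in _maximal_matches(seq, t, min_length, same_index):
            if orient in ("forward", "complemented"):
                j = k
            else:  # positions in a reversed string map back to n - k - length
                j = n - k - length
            loc1, loc2 = (i, i + length), (j, j + length)
            if loc1 == loc2:
                continue
            if loc2 < loc1:
                loc1, loc2 = loc2, loc1
            hits.add((loc1, loc2, orient))
    return sorted(
        (RepeatHit(locus1=a, locus2=b, orientation=o, length=a[1] - a[0],
                   identity=100.0)
         for a, b, o in hits),
        key=lambda h: (h.orientation, h.locus1, h.locus2),
    )


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def tandem_repeats(
    seq: str,
    min_unit: int = 11,
    min_copies: float = 2.0,
    max_unit: int = 120,
    max_mismatch_fraction: float = 0.20,
) -> list[TandemRepeat]:
    """Tandem arrays with unit length in [min_unit, max_unit].

    For each candidate period p the boolean profile ``seq[i] == seq[i+p]`` is
    scanned for anchors (exact runs of at least max(8, p//2) matches), which
    are then extended outwards while the mismatch fraction stays within
    ``max_mismatch_fraction``. Arrays reported at a smaller period suppress
    their harmonics.
    """
    if min_unit < 1:
        raise ValueError("min_unit must be >= 1")
    s = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(s)
    found: list[TandemRepeat] = []
    for p in range(min_unit, min(max_unit, n // 2) + 1):
        m = s[:-p] == s[p:]
        if not m.any():
            continue
        anchor_len = max(8, p // 2)
        padded = np.concatenate(([0], m.astype(np.int8), [0]))
        step = np.diff(padded)
        run_starts = np.flatnonzero(step == 1)
        run_ends = np.flatnonzero(step == -1)
        claimed_end = -1
        for rs, re_ in zip(run_starts, run_ends):
            if re_ - rs < anchor_len or rs < claimed_end:
                continue
            lo, hi = _extend_run(m, int(rs), int(re_), max_mismatch_fraction)
            locus = (lo, hi + p)
            copies = (locus[1] - locus[0]) / p
            if copies + 1e-9 < min_copies:
                continue
            claimed_end = hi
            if _is_harmonic(found, locus, p):
                continue
            found.append(
                TandemRepeat(locus=locus, period=p, copies=round(copies, 2),
                             consensus=_consensus(seq, locus, p))
            )
    return sorted(found, key=lambda r: (r.locus, r.period))


def _extend_run(m: np.ndarray, lo: int, hi: int, tol: float) -> tuple[int, int]:
    """Score-based X-drop extension of a perfect periodic run.

    Matches score +2 and mismatches -8 (an interior mismatch fraction of
    ~``tol``=0.2 is score-neutral); extension stops once the running score
    falls 30 below its maximum, and the run is trimmed back to the
    best-scoring boundary so flanking random sequence is not absorbed.
    """
    del tol  # fixed weights implement the 20% interior tolerance
    n = len(m)
    score = best = 0
    j = hi
    best_hi = hi
    while j < n:
        score += 2 if m[j] else -8
        j += 1
        if score > best:
            best, best_hi = score, j
        elif best - score > 30:
            break
    score = best = 0
    i = lo
    best_lo = lo
    while i > 0:
        score += 2 if m[i - 1] else -8
        i -= 1
        if score > best:
            best, best_lo = score, i
        elif best - score > 30:
            break
    return best_lo, best_hi


def _is_harmonic(found: list[TandemRepeat], locus: tuple[int, int],
                 period: int) -> bool:
    s, e = locus
    for r in found:
        if r.period >= period:
            continue
        overlap = max(0, min(e, r.locus[1]) - max(s, r.locus[0]))
        if overlap >= 0.8 * (e - s):
            return True
    return False


def _consensus(seq: str, locus: tuple[int, int], period: int) -> str:
    from collections import Counter

    s, e = locus
    cols: list[Counter] = [Counter() for _ in range(period)]
    for i in range(s, e):
        cols[(i - s) % period][seq[i]] += 1
    return "".join(c.most_common(1)[0][0] for c in cols)


def tandem_coverage_percent(repeats: list[TandemRepeat], genome_length: int) -> float:
    """Percent of the genome covered by the union of tandem-array loci."""
    if not repeats or genome_length == 0:
        return 0.0
    loci = sorted(r.locus for r in repeats)
    covered = 0
    cur_s, cur_e = loci[0]
    for s, e in loci[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return 100.0 * covered / genome_length


# ---------------------------------------------------------------------------
# Seeded local-alignment similarity hits
# ---------------------------------------------------------------------------

_WORD = 11
_XDROP = 12
_MATCH, _MISMATCH, _GAP = 1, -2, -2


def similarity_hits(
    query_set: list[str],
    subject_set: list[str],
    min_identity: float = 80.0,
    max_e: float = 1e-10,
    min_length: int = 30,
) -> list[RepeatHit]:
    """Local-alignment hits between two sequence sets (self-scan aware).

    When the sets are the same object (or positionally identical sequences),
    the trivial full-length self-hit of each sequence on its own diagonal is
    excluded, leaving only genuinely repeated segments.
    """
    queries = [q.upper() for q in query_set]
    subjects = [s.upper() for s in subject_set]
    total_subject = sum(len(s) for s in subjects) or 1
    hits: list[RepeatHit] = []
    for si, subj in enumerate(subjects):
        index: dict[str, list[int]] = {}
        for k in range(len(subj) - _WORD + 1):
            index.setdefault(subj[k : k + _WORD], []).append(k)
        for qi, query in enumerate(queries):
            self_scan = query == subj
            for strand in ("+", "-"):
                q = query if strand == "+" else revcomp(query)
                raw = _scan_one(q, subj, index, self_scan and strand == "+")
                for (qs, qe, ss, se, score, ident) in raw:
                    if strand == "-":
                        qs, qe = len(query) - qe, len(query) - qs
                    length = max(qe - qs, se - ss)
                    if length < min_length:
                        continue
                    evalue = KA_K * len(query) * total_subject * exp(
                        -KA_LAMBDA * score
                    )
                    if evalue > max_e or ident < min_identity:
                        continue
                    loc1, loc2 = (qs, qe), (ss, se)
                    if self_scan and loc1 == loc2:
                        continue
                    if self_scan and loc2 < loc1:
                        loc1, loc2 = loc2, loc1  # symmetric pair, report once
                    hits.append(RepeatHit(
                        locus1=loc1, locus2=loc2,
                        orientation="forward" if strand == "+" else "palindromic",
                        length=length, identity=round(ident, 2),
                        query_index=qi, subject_index=si,
                        score=score, evalue=evalue,
                    ))
    return _dedupe_hits(hits)


def _scan_one(q: str, subj: str, index: dict[str, list[int]],
              skip_diagonal: bool) -> list[tuple[int, int, int, int, float, float]]:
    """Ungapped X-drop extension of word seeds, one best HSP per diagonal
    region, followed by a local realignment for identity."""
    nq, ns = len(q), len(subj)
    seen: dict[int, int] = {}  # diagonal -> q end already covered
    out = []
    for i in range(nq - _WORD + 1):
        for k in index.get(q[i : i + _WORD], ()):  # noqa: B020
            diag = i - k
            if skip_diagonal and diag == 0:
                continue
            if seen.get(diag, -1) >= i:
                continue
            qs, qe, ss, se, score = _xdrop_extend(q, subj, i, k)
            seen[diag] = qe
            if score < 16:  # too weak for any E <= 1e-10 at these sizes
                continue
            ident = _segment_identity(q[qs:qe], subj[ss:se])
            out.append((qs, qe, ss, se, float(score), ident))
    return out


def _xdrop_extend(q: str, subj: str, i: int, k: int):
    nq, ns = len(q), len(subj)
    # right
    score = best = _WORD * _MATCH
    qe, se = i + _WORD, k + _WORD
    best_qe, best_se = qe, se
    while qe < nq and se < ns:
        score += _MATCH if q[qe] == subj[se] else _MISMATCH
        qe += 1
        se += 1
        if score > best:
            best, best_qe, best_se = score, qe, se
        elif best - score > _XDROP:
            break
    # left
    score = best
    qs, ss = i, k
    best_qs, best_ss = qs, ss
    while qs > 0 and ss > 0:
        score += _MATCH if q[qs - 1] == subj[ss - 1] else _MISMATCH
        qs -= 1
        ss -= 1
        if score > best:
            best, best_qs, best_ss = score, qs, ss
        elif best - score > _XDROP:
            break
    return best_qs, best_qe, best_ss, best_se, best


def _segment_identity(a: str, b: str) -> float:
    if len(a) == len(b):
        same = sum(1 for x, y in zip(a, b) if x == y)
        return 100.0 * same / len(a) if a else 0.0
    from .core_genes import align_pair

    ga, gb = align_pair(a, b)
    same = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return 100.0 * same / len(ga) if ga else 0.0


def _dedupe_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Keep the best-scoring hit among near-duplicate locus pairs."""
    kept: list[RepeatHit] = []
    for h in sorted(hits, key=lambda h: -(h.score or 0)):
        dup = False
        for k in kept:
            if (k.query_index, k.subject_index, k.orientation) != (
                h.query_index, h.subject_index, h.orientation
            ):
                continue
            if _overlap_frac(k.locus1, h.locus1) > 0.5 and \
               _overlap_frac(k.locus2, h.locus2) > 0.5:
                dup = True
                break
        if not dup:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.query_index, h.subject_index,
                                       h.locus1, h.locus2))


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    shorter = max(1, min(a[1] - a[0], b[1] - b[0]))
    return ov / shorter
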