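"""Shared-tRNA identification and cloverleaf-domain attribution of variable sites.

Mitochondrial tRNAs fold into the classical cloverleaf; a variable position
between two genomes is attributed to one of the structural domains

    acceptor_stem | d_arm | anticodon_arm | variable_region | t_arm | other

either from a dot-bracket secondary-structure annotation (preferred) or from a
fixed canonical position template. tRNAs are matched between genomes by
isoacceptor identity (amino acid + anticodon); isodecoders (several copies
with the same anticodon, e.g. the three trnM genes) are matched by their order
of appearance along the genome — arbitrary, but deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import pandas as pd

from .core_genes import align_pair
from .io import AnnotatedMitogenome, GeneFeature

DOMAINS = ("acceptor_stem", "d_arm", "anticodon_arm", "variable_region",
           "t_arm", "other")

#: observed tRNA gene length range in fungal mitogenomes; outside -> warning
LENGTH_RANGE = (71, 88)


# ---------------------------------------------------------------------------
# Cloverleaf templates and dot-bracket parsing
# ---------------------------------------------------------------------------


def cloverleaf_template(variable_len: int = 5) -> tuple[str, list[str]]:
    """(dot-bracket structure, per-position domain labels) for a canonical
    cloverleaf with a variable region of ``variable_len`` nt (5 for most
    tRNAs, ~14 for the long-armed serine/leucine tRNAs)."""
    segs = [
        ("acceptor_stem", "(" * 7),
        ("other", ".."),
        ("d_arm", "((((" + "." * 8 + "))))"),
        ("other", "."),
        ("anticodon_arm", "(((((" + "." * 7 + ")))))"),
        ("variable_region", "." * variable_len),
        ("t_arm", "(((((" + "." * 7 + ")))))"),
        ("acceptor_stem", ")" * 7),
        ("other", "."),  # discriminator base
    ]
    structure = "".join(s for _, s in segs)
    labels = [lab for lab, s in segs for _ in s]
    return structure, labels


def domains_from_structure(structure: str) -> list[str]:
    """Per-position domain labels parsed from a dot-bracket string.

    The three hairpins in 5'->3' order are the D, anticodon, and T arms; pairs
    enclosing all hairpins form the acceptor stem; unpaired stretch between
    the anticodon and T arms is the variable region.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")

    n = len(structure)
    labels = ["other"] * n

    # hairpin loops: unpaired runs directly enclosed by a pair
    hairpins: list[tuple[int, int]] = []  # (loop_start, loop_end) inclusive
    i = 0
    while i < n:
        if structure[i] == ".":
            j = i
            while j + 1 < n and structure[j + 1] == ".":
                j += 1
            if (i > 0 and j + 1 < n and structure[i - 1] == "("
                    and structure[j + 1] == ")" and pairs.get(i - 1) == j + 1):
                hairpins.append((i, j))
            i = j + 1
        else:
            i += 1

    arm_names = ["d_arm", "anticodon_arm", "t_arm"]
    if len(hairpins) != 3:
        # degenerate structure: fall back to positional template
        _, tmpl = cloverleaf_template(max(0, n - 68))
        return tmpl[:n] + ["other"] * max(0, n - len(tmpl))

    arm_bounds = []
    for (ls, le), name in zip(hairpins, arm_names):
        lo, hi = ls - 1, le + 1
        while lo - 1 >= 0 and pairs.get(lo - 1) == hi + 1:
            lo -= 1
            hi += 1
        for k in range(lo, hi + 1):
            labels[k] = name
        arm_bounds.append((lo, hi))

    # acceptor stem: remaining paired positions outside the three arms
    for i_, j_ in pairs.items():
        if labels[i_] == "other":
            labels[i_] = "acceptor_stem"
    # variable region: unpaired positions between anticodon arm and T arm
    ac_end, t_start = arm_bounds[1][1], arm_bounds[2][0]
    for k in range(ac_end + 1, t_start):
        if labels[k] == "other":
            labels[k] = "variable_region"
    return labels


def anticodon_positions(structure: str) -> tuple[int, int, int]:
    """The three central positions of the anticodon loop (0-based)."""
    labels = domains_from_structure(structure)
    arm = [i for i, lab in enumerate(labels) if lab == "anticodon_arm"
           and structure[i] == "."]
    if len(arm) < 3:
        raise ValueError("no anticodon loop found")
    mid = len(arm) // 2
    return arm[mid - 1], arm[mid], arm[mid + 1]


@dataclass
class TrnaDomainMap:
    name: str
    sequence: str
    labels: list[str]
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise ValueError(f"{self.name}: domain map length mismatch")
        lo, hi = LENGTH_RANGE
        if not lo <= len(self.sequence) <= hi:
            warn(f"tRNA {self.name} length {len(self.sequence)} outside "
                 f"the typical [{lo}, {hi}] bp range")


def domain_map(
    name: str,
    sequence: str,
    structure: str | None = None,
    anticodon: str | None = None,
) -> TrnaDomainMap:
    """Build a domain map from a dot-bracket structure, or from the canonical
    position template when no structure is supplied."""
    if structure is not None:
        labels = domains_from_structure(structure)
        if len(labels) != len(sequence):
            raise ValueError(f"{name}: structure/sequence length mismatch")
    else:
        _, labels = cloverleaf_template(max(0, len(sequence) - 68))
        labels = (labels + ["other"] * len(sequence))[: len(sequence)]
    return TrnaDomainMap(name=name, sequence=sequence, labels=labels,
                         anticodon=anticodon)


# ---------------------------------------------------------------------------
# Structure sidecar files (one record: >name / sequence / dot-bracket)
# ---------------------------------------------------------------------------


def write_structures(structures: dict[str, tuple[str, str]], path) -> None:
    with open(str(path), "w") as fh:
        for name, (seq, struct) in structures.items():
            fh.write(f">{name}\n{seq}\n{struct}\n")


def read_structures(path) -> dict[str, tuple[str, str]]:
    out: dict[str, tuple[str, str]] = {}
    with open(str(path)) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i in range(0, len(lines), 3):
        name = lines[i].lstrip(">")
        out[name] = (lines[i + 1], lines[i + 2])
    return out


# ---------------------------------------------------------------------------
# Matching and variation
# ---------------------------------------------------------------------------


def _trna_key(f: GeneFeature) -> tuple[str, str]:
    aa = f.name[3:4].upper() if f.name.lower().startswith("trn") else f.name
    return aa, (f.anticodon or "").lower()


def match_trnas(
    a: AnnotatedMitogenome, b: AnnotatedMitogenome
) -> tuple[list[tuple[GeneFeature, GeneFeature]], list[GeneFeature], list[GeneFeature]]:
    """Pair tRNA genes by (amino acid, anticodon); extra copies by genome order.

    Returns (matched pairs, unmatched in a, unmatched in b).
    """
    def by_key(genome):
        groups: dict[tuple[str, str], list[GeneFeature]] = {}
        for f in genome.features_of_kind("tRNA"):  # sorted by position
            groups.setdefault(_trna_key(f), []).append(f)
        return groups

    ga, gb = by_key(a), by_key(b)
    pairs, only_a, only_b = [], [], []
    for key in sorted(set(ga) | set(gb)):
        la, lb = ga.get(key, []), gb.get(key, [])
        for fa, fb in zip(la, lb):
            pairs.append((fa, fb))
        only_a.extend(la[len(lb):])
        only_b.extend(lb[len(la):])
    return pairs, only_a, only_b


@dataclass
class TrnaVariation:
    name: str
    positions: list[int]            # 0-based positions in the genome-a tRNA
    by_domain: dict[str, int]


@dataclass
class TrnaVariationReport:
    entries: list[TrnaVariation] = field(default_factory=list)

    @property
    def domain_totals(self) -> dict[str, int]:
        totals = {d: 0 for d in DOMAINS}
        for e in self.entries:
            for d, k in e.by_domain.items():
                totals[d] += k
        return totals

    @property
    def total_variable_sites(self) -> int:
        return sum(len(e.positions) for e in self.entries)

    @property
    def n_variable_trnas(self) -> int:
        return sum(1 for e in self.entries if e.positions)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"trna": e.name, "variable_sites": len(e.positions),
                 **{d: e.by_domain.get(d, 0) for d in DOMAINS}}
                for e in self.entries]
        return pd.DataFrame(rows).set_index("trna")


def variable_sites(
    seq_a: str, seq_b: str, domains: TrnaDomainMap, name: str = ""
) -> TrnaVariation:
    """Positions differing between a matched tRNA pair, attributed to domains.

    Equal-length pairs are compared position-wise; unequal pairs are globally
    aligned first and positions reported in genome-a coordinates.
    """
    positions: list[int] = []
    by_domain: dict[str, int] = {}
    if len(seq_a) == len(seq_b):
        cols = zip(seq_a.upper(), seq_b.upper())
        ia = -1
        for x, y in cols:
            ia += 1
            if x != y:
                positions.append(ia)
    else:
        ga, gb = align_pair(seq_a.upper(), seq_b.upper())
        ia = -1
        for x, y in zip(ga, gb):
            if x != "-":
                ia += 1
            if x != y and x != "-":
                positions.append(ia)
    for p in positions:
        lab = domains.labels[p] if p < len(domains.labels) else "other"
        by_domain[lab] = by_domain.get(lab, 0) + 1
    return TrnaVariation(name=name or domains.name, positions=positions,
                         by_domain=by_domain)


def compare_trnas(
    a: AnnotatedMitogenome,
    b: AnnotatedMitogenome,
    structures: dict[str, tuple[str, str]] | None = None,
) -> TrnaVariationReport:
    """Variable-site report over all tRNAs shared by two genomes."""
    pairs, _, _ = match_trnas(a, b)
    report = TrnaVariationReport()
    counters: dict[str, int] = {}
    for fa, fb in pairs:
        copy = counters.get(fa.name, 0)
        counters[fa.name] = copy + 1
        label = fa.name if copy == 0 else f"{fa.name}.{copy + 1}"
        seq_a, seq_b = a.extract(fa), b.extract(fb)
        struct = None
        if structures:
            rec = structures.get(label) or structures.get(fa.name)
            if rec is not None:
                struct = rec[1]
        dm = domain_map(label, seq_a, structure=struct, anticodon=fa.anticodon)
        report.entries.append(variable_sites(seq_a, seq_b, dm, name=label))
    return report
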