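"""Synthetic annotated mitogenome pairs with fully known ground truth.

The generator builds an AT-rich circular genome gene-by-gene (15 core protein
genes, two rRNAs, 25 cloverleaf tRNAs, hypothetical ORFs, group-I introns,
spacers) and derives a diverged sister genome from it under a
Kimura-two-parameter substitution process with planned per-gene rates, intron
gain/loss, tRNA domain mutations, and planted repeats. Every planted quantity
is recorded in a truth table so each analysis stage can be validated against
known structure rather than against itself.

The default :class:`GeneratorSpec` emulates a two-species comparison of
medium-size fungal mitogenomes: 66,704 vs 77,109 bp, ~78.5% AT with negative
AT skew and positive GC skew on the forward strand, 16 vs 24 group-I introns
arranged so intron turnover dominates the size difference, conserved gene
order, and purifying-selection-like codon-position bias in the substitution
process (most changes land on third positions).

Substitutions in coding genes that would create an in-frame stop codon are
re-targeted to another base — a mild departure from a free K2P process that
keeps the synthetic annotations valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codon import STOP_CODONS_4, complement, revcomp
from .io import AnnotatedMitogenome, GeneFeature
from .trna import anticodon_positions, cloverleaf_template

# forward-strand base probabilities: 78.5% AT with mild asymmetry giving a
# negative AT skew and positive GC skew, as in AT-rich fungal mitogenomes
BASE_PROBS = {"A": 0.375, "C": 0.100, "G": 0.115, "T": 0.410}

CORE_LENGTHS = {
    "atp6": 780, "atp8": 159, "atp9": 225, "cob": 1161, "cox1": 1608,
    "cox2": 750, "cox3": 810, "nad1": 1080, "nad2": 1680, "nad3": 420,
    "nad4": 1488, "nad4L": 270, "nad5": 1980, "nad6": 660, "rps3": 1380,
}
RRNA_LENGTHS = {"rnl": 3200, "rns": 1600}

#: codons removed just before the stop codon in the sister genome
B_CODON_DELETIONS = {"nad3": 7, "nad4": 2, "rps3": 20}

START_CODONS = {"cox1": "TTG"}
STOP_CODONS = {"cob": "TAG"}

# (amino acid letter, anticodon, long variable arm?) for the 25 tRNAs
TRNA_ROSTER: list[tuple[str, str, str, bool]] = [
    ("trnA", "A", "tgc", False), ("trnC", "C", "gca", False),
    ("trnD", "D", "gtc", False), ("trnE", "E", "ttc", False),
    ("trnF", "F", "gaa", False), ("trnG", "G", "tcc", False),
    ("trnH", "H", "gtg", False), ("trnI", "I", "gat", False),
    ("trnK", "K", "ttt", False), ("trnL1", "L", "tag", True),
    ("trnL2", "L", "taa", True), ("trnM", "M", "cat", False),
    ("trnN", "N", "gtt", False), ("trnP", "P", "tgg", False),
    ("trnQ", "Q", "ttg", False), ("trnR1", "R", "tct", False),
    ("trnR2", "R", "acg", False), ("trnS1", "S", "tga", True),
    ("trnS2", "S", "gct", True), ("trnT", "T", "tgt", False),
    ("trnV", "V", "tac", False), ("trnW", "W", "tca", False),
    ("trnY", "Y", "gta", False),
]  # trnM appears three times (isodecoders) in the gene order below


@dataclass(frozen=True)
class IntronPlan:
    host: str
    coordinate: int      # nt of host coding/structural sequence before intron
    length: int
    sharing: str         # 'shared' | 'a_only' | 'b_only'
    identity: float = 0.97
    group: str = "IB"
    n_orfs: int = 1      # intronic homing-endonuclease ORFs to embed


def _default_intron_plan() -> tuple[IntronPlan, ...]:
    mk = IntronPlan
    return (
        # cox1: 4 shared + 5 sister-only position classes
        mk("cox1", 222, 1400, "shared"),
        mk("cox1", 387, 1400, "shared", n_orfs=0),
        mk("cox1", 708, 1400, "shared"),
        mk("cox1", 1125, 1400, "shared", n_orfs=0),
        mk("cox1", 150, 1600, "b_only", n_orfs=2),
        mk("cox1", 501, 1600, "b_only"),
        mk("cox1", 933, 1600, "b_only"),
        mk("cox1", 1251, 1600, "b_only"),
        mk("cox1", 1420, 1600, "b_only"),
        # cox2: the genome-a-specific intron at 543 nt
        mk("cox2", 543, 1200, "a_only"),
        # cob: 6 shared + 1 sister-only (1/7 non-homologous)
        mk("cob", 108, 1400, "shared"),
        mk("cob", 210, 1400, "shared", n_orfs=0),
        mk("cob", 336, 1400, "shared"),
        mk("cob", 480, 1400, "shared", n_orfs=0),
        mk("cob", 642, 1400, "shared"),
        mk("cob", 891, 1400, "shared", n_orfs=0),
        mk("cob", 1020, 1600, "b_only", group="novel"),
        # cox3: 1 shared + 1 sister-only (50%)
        mk("cox3", 300, 1400, "shared"),
        mk("cox3", 555, 1600, "b_only"),
        # nad5: 2 shared + 1 a-only + 2 b-only (60%)
        mk("nad5", 400, 1400, "shared", n_orfs=0),
        mk("nad5", 900, 1400, "shared"),
        mk("nad5", 1300, 1250, "a_only"),
        mk("nad5", 600, 1600, "b_only"),
        mk("nad5", 1500, 1600, "b_only"),
        # rnl: fully non-homologous (100%)
        mk("rnl", 800, 1150, "a_only", group="novel"),
        mk("rnl", 1200, 1600, "b_only", group="ID", n_orfs=0),
        mk("rnl", 2100, 1572, "b_only", group="ID"),
    )


#: reference letter names for cox1 position classes (coordinate -> letter)
DEFAULT_COX1_EXEMPLARS = {222: "K", 387: "S", 708: "AC", 1125: "AD",
                          150: "D", 501: "G", 933: "H"}


@dataclass(frozen=True)
class DivergencePlan:
    rate: float          # expected substitutions per site
    syn_weight: float = 8.0   # relative weight of third codon positions
    syn_only: bool = False


def _default_divergence() -> dict[str, DivergencePlan]:
    d = DivergencePlan
    return {
        "atp6": d(0.020), "atp8": d(0.012, syn_only=True), "atp9": d(0.004),
        "cob": d(0.022), "cox1": d(0.018), "cox2": d(0.025),
        "cox3": d(0.050, syn_weight=16.0), "nad1": d(0.028), "nad2": d(0.030),
        "nad3": d(0.035), "nad4": d(0.026), "nad4L": d(0.015),
        "nad5": d(0.024), "nad6": d(0.055), "rps3": d(0.080, syn_weight=2.0),
    }


@dataclass(frozen=True)
class TrnaMutationPlan:
    trna: str
    domain: str
    count: int


def _default_trna_mutations() -> tuple[TrnaMutationPlan, ...]:
    m = TrnaMutationPlan
    return (
        m("trnA", "acceptor_stem", 1), m("trnC", "acceptor_stem", 1),
        m("trnD", "acceptor_stem", 2), m("trnE", "acceptor_stem", 1),
        m("trnF", "acceptor_stem", 1),
        m("trnG", "d_arm", 1), m("trnH", "d_arm", 1), m("trnK", "d_arm", 2),
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Complete description of a synthetic two-genome comparison."""

    seed: int = 0
    id_a: str = "synthA"
    id_b: str = "synthB"
    size_a: int = 66_704
    size_b: int = 77_109
    kappa: float = 2.0
    intron_plan: tuple[IntronPlan, ...] = field(
        default_factory=_default_intron_plan)
    divergence: dict[str, DivergencePlan] = field(
        default_factory=_default_divergence)
    rrna_rate: float = 0.02
    orf_rate: float = 0.03
    b_codon_deletions: dict[str, int] = field(
        default_factory=lambda: dict(B_CODON_DELETIONS))
    trna_mutations: tuple[TrnaMutationPlan, ...] = field(
        default_factory=_default_trna_mutations)
    duplicate_length: int = 810
    duplicate_identity: float = 0.95
    tandem_high_copy: tuple[int, int] = (12, 13)   # (unit, copies) in genome b
    tandem_long: tuple[int, int] = (29, 4)         # longest array in genome b
    tandem_a: tuple[int, int] = (20, 3)            # one array in genome a
    exact_pair_length: int = 50
    palindrome_length: int = 40
    tree: str = ("((Rhizopogon_A:0.02,Rhizopogon_B:0.025):0.15,"
                 "(Suillus_C:0.18,Boletus_D:0.22):0.05,Paxillus_E:0.30);")


# gene orders (None entries are genome-b-only / genome-a-only markers)
_A_ORDER = [
    "trnM", "cox1", "trnR1", "nad1", "trnP", "nad4", "trnQ", "orf105",
    "trnY", "rns", "trnS1", "cox2", "trnL1", "atp9", "trnI", "cob", "trnF",
    "nad2", "trnW", "nad3", "trnH", "orf201", "trnK", "nad4L", "nad5",
    "trnT", "atp6", "trnV", "atp8", "trnG", "rnl", "trnL2", "orf232",
    "rps3", "trnA", "cox3", "orf632", "trnN", "nad6", "trnM", "orf249",
    "trnS2", "orf300", "trnD", "trnR2", "orf438", "trnC", "trnE", "trnM",
]
_B_REMOVED = {"orf249", "orf300", "orf438"}
_MINUS_STRAND = {"nad2", "trnW", "nad3", "trnH"}
_ORF_LENGTHS = {"orf105": 318, "orf201": 606, "orf232": 699, "orf249": 750,
                "orf300": 903, "orf438": 1317, "orf632": 1899, "orf641": 1926}
_OVERLAP_BP = 85  # cox3 tail shared with the downstream hypothetical ORF


# ---------------------------------------------------------------------------
# Random-sequence primitives
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGT"
_PROBS = np.array([BASE_PROBS[b] for b in _BASE_ORDER])


def random_seq(rng: np.random.Generator, n: int) -> str:
    idx = rng.choice(4, size=n, p=_PROBS)
    return "".join(_BASE_ORDER[i] for i in idx)


def random_cds(rng: np.random.Generator, length: int, start: str, stop: str) -> str:
    """Random in-frame CDS at the background composition, no internal stops."""
    assert length % 3 == 0 and length >= 6
    codons = []
    while len(codons) < length // 3 - 2:
        c = random_seq(rng, 3)
        if c not in STOP_CODONS_4:
            codons.append(c)
    return start + "".join(codons) + stop


def random_trna(rng: np.random.Generator, anticodon: str,
                long_arm: bool) -> tuple[str, str]:
    """(sequence, dot-bracket) for one cloverleaf tRNA gene."""
    structure, _ = cloverleaf_template(14 if long_arm else 5)
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs[stack.pop()] = i
    seq = [""] * len(structure)
    for i, ch in enumerate(structure):
        if seq[i]:
            continue
        b = _BASE_ORDER[rng.choice(4, p=_PROBS)]
        seq[i] = b
        if i in pairs:
            seq[pairs[i]] = complement(b)
    for pos, b in zip(anticodon_positions(structure), anticodon.upper()):
        seq[pos] = b
    return "".join(seq), structure


# ---------------------------------------------------------------------------
# K2P-style mutation with frame awareness
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _propose(rng: np.random.Generator, base: str, kappa: float) -> list[str]:
    """Candidate replacement bases, most preferred first."""
    tv = list(_TRANSVERSIONS[base])
    if rng.random() < kappa / (kappa + 2.0):
        order = [_TRANSITION[base]] + list(rng.permutation(tv))
    else:
        tv = list(rng.permutation(tv))
        order = tv[:1] + [_TRANSITION[base]] + tv[1:]
    return order


def mutate_plain(rng: np.random.Generator, seq: str, rate: float,
                 kappa: float = 2.0) -> tuple[str, int]:
    """Substitute ~rate fraction of sites (transition:transversion per kappa)."""
    n = len(seq)
    m = rng.binomial(n, rate)
    if m == 0:
        return seq, 0
    sites = rng.choice(n, size=m, replace=False)
    out = list(seq)
    for i in sites:
        out[i] = _propose(rng, out[i], kappa)[0]
    return "".join(out), m


def mutate_cds(rng: np.random.Generator, cds: str, plan: DivergencePlan,
               kappa: float) -> tuple[str, int]:
    """Frame-aware substitution of a CDS: start/stop codons untouched, no
    in-frame stops created; third codon positions weighted ``syn_weight``."""
    from ._codon import GENETIC_CODE_4

    n = len(cds)
    out = list(cds)
    eligible = np.arange(3, n - 3)
    if plan.syn_only:
        # third positions where a transition is synonymous and not a stop
        sites = []
        for i in range(3, n - 3):
            if i % 3 != 2:
                continue
            codon = cds[i - 2 : i + 1]
            alt = codon[:2] + _TRANSITION[codon[2]]
            if (alt not in STOP_CODONS_4
                    and GENETIC_CODE_4.get(alt) == GENETIC_CODE_4.get(codon)):
                sites.append(i)
        m = min(rng.binomial(n, plan.rate), len(sites))
        chosen = rng.choice(sites, size=m, replace=False) if m else []
        for i in chosen:
            out[i] = _TRANSITION[out[i]]
        return "".join(out), int(m)

    weights = np.where(eligible % 3 == 2, plan.syn_weight, 1.0)
    weights = weights / weights.sum()
    m = rng.binomial(n, plan.rate)
    m = min(m, len(eligible))
    chosen = rng.choice(eligible, size=m, replace=False, p=weights) if m else []
    applied = 0
    for i in chosen:
        codon_start = i - i % 3
        for cand in _propose(rng, out[i], kappa):
            codon = "".join(out[codon_start : codon_start + 3])
            new_codon = (codon[: i % 3] + cand + codon[i % 3 + 1 :])
            if new_codon not in STOP_CODONS_4:
                out[i] = cand
                applied += 1
                break
    return "".join(out), applied


def mutate_to_identity(rng: np.random.Generator, seq: str, identity: float,
                       kappa: float = 2.0) -> str:
    mutated, _ = mutate_plain(rng, seq, 1.0 - identity, kappa)
    return mutated


# ---------------------------------------------------------------------------
# Element model and assembly
# ---------------------------------------------------------------------------


@dataclass
class _NestedOrf:
    name: str
    offset: int  # within the intron (sense orientation)
    length: int
    product: str


@dataclass
class _Part:
    kind: str   # 'exon' | 'intron'
    seq: str
    group: str = ""
    orfs: list[_NestedOrf] = field(default_factory=list)


@dataclass
class _Element:
    name: str
    kind: str   # 'CDS' | 'ORF' | 'tRNA' | 'rRNA' | 'spacer'
    parts: list[_Part]
    strand: str = "+"
    product: str = ""
    anticodon: str | None = None
    overlap_prev: int = 0
    content_offset: int | None = None  # planted-content offset for spacers
    content_length: int = 0

    @property
    def seq(self) -> str:
        return "".join(p.seq for p in self.parts)

    @property
    def length(self) -> int:
        return len(self.seq)


def _assemble(genome_id: str, elements: list[_Element]
              ) -> tuple[AnnotatedMitogenome, dict[int, tuple[int, int]]]:
    """Lay elements around the circle; returns the genome and each element's
    genomic (start, end)."""
    chunks: list[str] = []
    pos = 0
    features: list[GeneFeature] = []
    spans: dict[int, tuple[int, int]] = {}
    orf_counter = [900]
    for idx, el in enumerate(elements):
        sense = el.seq
        written = revcomp(sense) if el.strand == "-" else sense
        if el.overlap_prev:
            ov = el.overlap_prev
            prev = "".join(chunks)[-ov:]
            if written[:ov] != prev:
                raise ValueError(f"{el.name}: inconsistent planned overlap")
            written = written[ov:]
            start = pos - ov
        else:
            start = pos
        chunks.append(written)
        pos = start + el.length
        spans[idx] = (start, pos)
        if el.kind == "spacer":
            continue
        # interval walk in forward-strand order
        parts_fwd = el.parts if el.strand == "+" else list(reversed(el.parts))
        exon_iv: list[tuple[int, int]] = []
        cur = start
        for part in parts_fwd:
            seg = (cur, cur + len(part.seq))
            cur = seg[1]
            if part.kind == "exon":
                exon_iv.append(seg)
            else:
                features.append(GeneFeature(
                    name=f"{el.name}-intron", kind="intron",
                    intervals=(seg,), strand=el.strand,
                    product=f"group {part.group} intron" if part.group else "",
                ))
                for orf in part.orfs:
                    if el.strand == "+":
                        s = seg[0] + orf.offset
                    else:
                        s = seg[0] + (len(part.seq) - orf.offset - orf.length)
                    orf_counter[0] += 1
                    features.append(GeneFeature(
                        name=orf.name, kind="ORF",
                        intervals=((s, s + orf.length),), strand=el.strand,
                        product=orf.product,
                    ))
        features.append(GeneFeature(
            name=el.name, kind=el.kind, intervals=tuple(exon_iv),
            strand=el.strand, product=el.product, anticodon=el.anticodon,
        ))
    return (
        AnnotatedMitogenome(id=genome_id, sequence="".join(chunks),
                            circular=True, features=features),
        spans,
    )


def _with_introns(cds: str, introns: list[tuple[IntronPlan, str]],
                  orf_names: list[str]) -> list[_Part]:
    """Split a sense sequence into exon/intron parts at planned coordinates."""
    parts: list[_Part] = []
    prev = 0
    for plan, iseq in sorted(introns, key=lambda x: x[0].coordinate):
        c = plan.coordinate
        if not prev <= c <= len(cds):
            raise ValueError(f"{plan.host}: intron coordinate {c} out of range")
        parts.append(_Part("exon", cds[prev:c]))
        orfs = []
        for k in range(plan.n_orfs):
            name = orf_names.pop(0)
            length = 300
            offset = 120 + k * 420
            product = ("LAGLIDADG homing endonuclease" if k % 2 == 0
                       else "GIY-YIG endonuclease")
            orfs.append(_NestedOrf(name=name, offset=offset, length=length,
                                   product=product))
        parts.append(_Part("intron", iseq, group=plan.group, orfs=orfs))
        prev = c
    parts.append(_Part("exon", cds[prev:]))
    return parts


# ---------------------------------------------------------------------------
# The generator proper
# ---------------------------------------------------------------------------


def generate_pair(spec: GeneratorSpec | None = None
                  ) -> tuple[AnnotatedMitogenome, AnnotatedMitogenome, dict]:
    """Build the genome pair and the truth tables of every planted quantity."""
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"spec_seed": spec.seed}

    # --- genome-a building blocks ---------------------------------------
    cds_a: dict[str, str] = {}
    for gene, length in CORE_LENGTHS.items():
        cds_a[gene] = random_cds(
            rng, length, START_CODONS.get(gene, "ATG"),
            STOP_CODONS.get(gene, "TAA"),
        )
    rrna_a = {g: random_seq(rng, n) for g, n in RRNA_LENGTHS.items()}
    trna_seqs: dict[str, tuple[str, str]] = {}
    for name, _aa, anticodon, long_arm in TRNA_ROSTER:
        trna_seqs[name] = random_trna(rng, anticodon, long_arm)
    orf_seq_a: dict[str, str] = {}
    for name in ("orf105", "orf201", "orf232", "orf249", "orf300", "orf438"):
        orf_seq_a[name] = random_seq(rng, _ORF_LENGTHS[name])
    orf_seq_a["orf632"] = (cds_a["cox3"][-_OVERLAP_BP:]
                           + random_seq(rng, _ORF_LENGTHS["orf632"] - _OVERLAP_BP))

    intron_seq_a: dict[tuple[str, int], str] = {}
    intron_seq_b: dict[tuple[str, int], str] = {}
    for plan in spec.intron_plan:
        key = (plan.host, plan.coordinate)
        if plan.sharing in ("shared", "a_only"):
            intron_seq_a[key] = random_seq(rng, plan.length)
        if plan.sharing == "shared":
            intron_seq_b[key] = mutate_to_identity(
                rng, intron_seq_a[key], plan.identity, spec.kappa)
        elif plan.sharing == "b_only":
            intron_seq_b[key] = random_seq(rng, plan.length)

    # --- genome-b derived sequences --------------------------------------
    cds_b: dict[str, str] = {}
    realized: dict[str, int] = {}
    for gene, seq in cds_a.items():
        plan = spec.divergence[gene]
        mutated, m = mutate_cds(rng, seq, plan, spec.kappa)
        if gene in spec.b_codon_deletions:
            k = spec.b_codon_deletions[gene]
            mutated = mutated[: -3 * (k + 1)] + mutated[-3:]
        cds_b[gene] = mutated
        realized[gene] = m
    rrna_b = {}
    rrna_realized = {}
    for g, seq in rrna_a.items():
        rrna_b[g], rrna_realized[g] = mutate_plain(rng, seq, spec.rrna_rate,
                                                   spec.kappa)
    trna_b: dict[str, str] = {n: s for n, (s, _) in trna_seqs.items()}
    trna_truth: list[dict] = []
    for mplan in spec.trna_mutations:
        seq = trna_b[mplan.trna]
        structure = trna_seqs[mplan.trna][1]
        from .trna import domains_from_structure

        labels = domains_from_structure(structure)
        ac_pos = set(anticodon_positions(structure))
        candidates = [i for i, lab in enumerate(labels)
                      if lab == mplan.domain and i not in ac_pos]
        chosen = rng.choice(candidates, size=mplan.count, replace=False)
        out = list(seq)
        for i in sorted(int(c) for c in chosen):
            alts = [b for b in _BASE_ORDER if b != out[i]]
            out[i] = alts[rng.integers(len(alts))]
        trna_b[mplan.trna] = "".join(out)
        trna_truth.append({"trna": mplan.trna, "domain": mplan.domain,
                           "count": mplan.count,
                           "positions": sorted(int(c) for c in chosen)})
    orf_seq_b = {
        name: mutate_plain(rng, orf_seq_a[name], spec.orf_rate, spec.kappa)[0]
        for name in ("orf105", "orf201", "orf232")
    }
    orf_seq_b["orf641"] = (cds_b["cox3"][-_OVERLAP_BP:]
                           + random_seq(rng, _ORF_LENGTHS["orf641"] - _OVERLAP_BP))

    # --- planted repeats (genome b, one tandem in genome a) ---------------
    dup = random_seq(rng, spec.duplicate_length)
    dup2 = mutate_to_identity(rng, dup, spec.duplicate_identity, spec.kappa)
    unit_hc = random_seq(rng, spec.tandem_high_copy[0])
    tandem_hc = unit_hc * spec.tandem_high_copy[1]
    unit_long = random_seq(rng, spec.tandem_long[0])
    tandem_long = unit_long * spec.tandem_long[1]
    unit_a = random_seq(rng, spec.tandem_a[0])
    tandem_a = unit_a * spec.tandem_a[1]
    exact_seg = random_seq(rng, spec.exact_pair_length)
    palin = random_seq(rng, spec.palindrome_length)

    # --- element lists ----------------------------------------------------
    intron_orf_names_a = [f"orf9{i:02d}" for i in range(1, 40)]
    intron_orf_names_b = [f"orf8{i:02d}" for i in range(1, 40)]

    def gene_element(name: str, genome: str) -> _Element:
        cds = (cds_a if genome == "a" else cds_b)
        rrna = (rrna_a if genome == "a" else rrna_b)
        iseq = (intron_seq_a if genome == "a" else intron_seq_b)
        orfnames = (intron_orf_names_a if genome == "a" else intron_orf_names_b)
        strand = "-" if name in _MINUS_STRAND else "+"
        if name in CORE_LENGTHS:
            introns = [(p, iseq[(p.host, p.coordinate)])
                       for p in spec.intron_plan
                       if p.host == name and (p.host, p.coordinate) in iseq]
            return _Element(name=name, kind="CDS",
                            parts=_with_introns(cds[name], introns, orfnames),
                            strand=strand, product=f"{name} protein")
        if name in RRNA_LENGTHS:
            introns = [(p, iseq[(p.host, p.coordinate)])
                       for p in spec.intron_plan
                       if p.host == name and (p.host, p.coordinate) in iseq]
            return _Element(name=name, kind="rRNA",
                            parts=_with_introns(rrna[name], introns, orfnames),
                            strand=strand,
                            product="large subunit ribosomal RNA"
                            if name == "rnl" else
                            "small subunit ribosomal RNA")
        if name.startswith("orf"):
            seq = (orf_seq_a if genome == "a" else orf_seq_b)[name]
            ov = _OVERLAP_BP if name in ("orf632", "orf641") else 0
            return _Element(name=name, kind="ORF",
                            parts=[_Part("exon", seq)], strand="+",
                            product="hypothetical protein", overlap_prev=ov)
        # tRNA
        seq = trna_seqs[name][0] if genome == "a" else trna_b[name]
        anticodon = next(ac for n, _aa, ac, _l in TRNA_ROSTER if n == name)
        return _Element(name=name, kind="tRNA", parts=[_Part("exon", seq)],
                        strand=strand, product=f"tRNA-{name[3]}",
                        anticodon=anticodon)

    def build_genome(genome: str):
        order = (_A_ORDER if genome == "a"
                 else [g if g != "orf632" else "orf641"
                       for g in _A_ORDER if g not in _B_REMOVED])
        gene_els = [gene_element(name, genome) for name in order]
        fixed_bp = sum(el.length - el.overlap_prev for el in gene_els)
        target = spec.size_a if genome == "a" else spec.size_b
        # a spacer precedes every element except overlapping ORFs, which abut
        # their upstream gene directly
        spacer_slots = [j for j, el in enumerate(gene_els)
                        if el.overlap_prev == 0]

        # planted spacer contents, keyed by the element the spacer follows;
        # guard bases inside the content strings stop accidental maximal
        # extension of the planted exact/palindromic pairs
        planted: dict[str, str] = {}
        if genome == "b":
            planted = {
                "orf105": dup, "orf232": dup2,
                "orf201": tandem_hc, "rnl": tandem_long,
                "trnK": "G" + exact_seg + "C",
                "trnV": "C" + exact_seg + "G",
                "trnT": ("G" + palin + random_seq(rng, 100)
                         + revcomp(palin) + "G"),
            }
        else:
            planted = {"rns": tandem_a}
        planted_idx: dict[int, str] = {}
        for i, name in enumerate(order):
            if name in planted:
                j = (i + 1) % len(gene_els)
                if j in spacer_slots:
                    planted_idx[j] = name
        fixed_lengths: dict[int, int] = {}
        after_orf105 = next(i for i, n in enumerate(order) if n == "orf105")
        fixed_lengths[(after_orf105 + 1) % len(gene_els)] = 1791
        after_atp9 = next(i for i, n in enumerate(order) if n == "atp9")
        fixed_lengths[(after_atp9 + 1) % len(gene_els)] = 37
        for j, src in planted_idx.items():
            need = len(planted[src]) + 80
            fixed_lengths[j] = max(fixed_lengths.get(j, 0), need)

        total_intergenic = target - fixed_bp
        free = [j for j in spacer_slots if j not in fixed_lengths]
        remaining = total_intergenic - sum(fixed_lengths.values())
        if remaining < 25 * len(free):
            raise ValueError("infeasible packing: genome target too small")
        w = rng.uniform(0.5, 1.5, size=len(free))
        raw = np.floor(w / w.sum() * (remaining - 25 * len(free))).astype(int)
        lengths = dict(fixed_lengths)
        for j, extra in zip(free, raw):
            lengths[j] = 25 + int(extra)
        lengths[free[-1]] += total_intergenic - sum(lengths.values())

        elements: list[_Element] = []
        for j, name in enumerate(order):
            if j in spacer_slots:
                L = lengths[j]
                if j in planted_idx:
                    content = planted[planted_idx[j]]
                    lpad = (L - len(content)) // 2
                    seq = (random_seq(rng, lpad) + content
                           + random_seq(rng, L - len(content) - lpad))
                    el = _Element(name=f"igs{j}", kind="spacer",
                                  parts=[_Part("exon", seq)],
                                  content_offset=lpad,
                                  content_length=len(content))
                else:
                    el = _Element(name=f"igs{j}", kind="spacer",
                                  parts=[_Part("exon", random_seq(rng, L))])
                elements.append(el)
            elements.append(gene_els[j])
        genome_obj, spans = _assemble(
            spec.id_a if genome == "a" else spec.id_b, elements)
        # locate planted content in genome coordinates
        content_loci: dict[str, tuple[int, int]] = {}
        for k, el in enumerate(elements):
            if el.kind == "spacer" and el.content_offset is not None:
                s = spans[k][0] + el.content_offset
                j = int(el.name[3:])
                content_loci[planted_idx[j]] = (s, s + el.content_length)
        region = {
            "protein_coding": sum(
                sum(len(p.seq) for p in el.parts if p.kind == "exon")
                for el in elements if el.kind in ("CDS", "ORF")
            ) - _OVERLAP_BP,
            "rna": sum(
                sum(len(p.seq) for p in el.parts if p.kind == "exon")
                for el in elements if el.kind in ("tRNA", "rRNA")
            ),
            "intronic": sum(
                len(p.seq) for el in elements for p in el.parts
                if p.kind == "intron"
            ),
            "intergenic": sum(
                el.length for el in elements if el.kind == "spacer"
            ),
        }
        assert sum(region.values()) == target, "element bookkeeping is off"
        return genome_obj, content_loci, region

    genome_a, loci_a, region_a = build_genome("a")
    genome_b, loci_b, region_b = build_genome("b")

    # --- truth tables ----------------------------------------------------
    size_diff = spec.size_b - spec.size_a
    truth.update({
        "sizes": {"a": spec.size_a, "b": spec.size_b},
        "at_content_plan": 100.0 * (BASE_PROBS["A"] + BASE_PROBS["T"]),
        "intron_counts": {
            "a": sum(p.sharing in ("shared", "a_only") for p in spec.intron_plan),
            "b": sum(p.sharing in ("shared", "b_only") for p in spec.intron_plan),
        },
        "introns": [
            {"host": p.host, "coordinate": p.coordinate, "length": p.length,
             "sharing": p.sharing, "identity": p.identity, "group": p.group}
            for p in spec.intron_plan
        ],
        "pcl_expected": _pcl_expectations(spec.intron_plan),
        "divergence": {
            g: {"rate": spec.divergence[g].rate, "realized": realized[g],
                "length_a": len(cds_a[g]), "length_b": len(cds_b[g]),
                "syn_only": spec.divergence[g].syn_only}
            for g in CORE_LENGTHS
        },
        "kappa": spec.kappa,
        "rrna_realized": rrna_realized,
        "trna_mutations": trna_truth,
        "trna_domain_totals": _domain_totals(spec.trna_mutations),
        "start_codons": {g: START_CODONS.get(g, "ATG") for g in CORE_LENGTHS},
        "stop_codons": {g: STOP_CODONS.get(g, "TAA") for g in CORE_LENGTHS},
        "overlap": {"a": ("cox3", "orf632", _OVERLAP_BP),
                    "b": ("cox3", "orf641", _OVERLAP_BP)},
        "duplicate": {
            "length": spec.duplicate_length,
            "identity": spec.duplicate_identity,
            "loci": [loci_b.get("orf105"), loci_b.get("orf232")],
        },
        "tandems": [
            {"genome": "b", "unit": spec.tandem_high_copy[0],
             "copies": spec.tandem_high_copy[1], "locus": loci_b.get("orf201")},
            {"genome": "b", "unit": spec.tandem_long[0],
             "copies": spec.tandem_long[1], "locus": loci_b.get("rnl")},
            {"genome": "a", "unit": spec.tandem_a[0],
             "copies": spec.tandem_a[1], "locus": loci_a.get("rns")},
        ],
        "exact_pair": {"length": spec.exact_pair_length,
                       "loci": [_inner(loci_b.get("trnK")),
                                _inner(loci_b.get("trnV"))]},
        "palindrome": {"length": spec.palindrome_length,
                       "loci": _palindrome_loci(loci_b.get("trnT"),
                                                spec.palindrome_length)},
        "region_lengths": {"a": region_a, "b": region_b},
        "decomposition": {
            c: 100.0 * (region_b[c] - region_a[c]) / size_diff
            for c in ("protein_coding", "intronic", "rna", "intergenic")
        },
        "breakpoint_distance": 0,
        "structures": {name: trna_seqs[name] for name in trna_seqs},
        "cox1_exemplars": dict(DEFAULT_COX1_EXEMPLARS),
        "tree": spec.tree,
        "sister_pair": ("Rhizopogon_A", "Rhizopogon_B"),
    })
    return genome_a, genome_b, truth


def _inner(locus: tuple[int, int] | None) -> tuple[int, int] | None:
    """Strip the one-base guard flanks around a planted exact segment."""
    if locus is None:
        return None
    return locus[0] + 1, locus[1] - 1


def _palindrome_loci(locus: tuple[int, int] | None, length: int):
    if locus is None:
        return None
    s, e = locus
    return (s + 1, s + 1 + length), (e - 1 - length, e - 1)


def _pcl_expectations(plans: tuple[IntronPlan, ...]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for p in plans:
        row = out.setdefault(p.host, {"shared": 0, "a_only": 0, "b_only": 0})
        row[p.sharing] += 1
    for row in out.values():
        total = row["shared"] + row["a_only"] + row["b_only"]
        row["total"] = total
        row["fraction_non_homologous"] = (
            100.0 * (row["a_only"] + row["b_only"]) / total
        )
    return out


def _domain_totals(plans: tuple[TrnaMutationPlan, ...]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for p in plans:
        totals[p.domain] = totals.get(p.domain, 0) + p.count
    return totals


# ---------------------------------------------------------------------------
# Sequence evolution along a tree
# ---------------------------------------------------------------------------


def _k2p_transition_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """(same, transition, each transversion) probabilities at distance d."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(
        -2.0 * (alpha_t + beta_t))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * beta_t)
    return 1.0 - p_ts - 2.0 * p_tv_each, p_ts, p_tv_each


_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T in ACGT encoding
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def simulate_alignment(tree: str, length: int, kappa: float = 2.0,
                       seed: int = 0) -> dict[str, str]:
    """Evolve i.i.d. columns along a newick tree under the K2P model.

    Branch lengths are in substitutions/site; returns taxon -> sequence.
    """
    import dendropy

    t = dendropy.Tree.get(data=tree, schema="newick",
                          preserve_underscores=True)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    seqs: dict[str, np.ndarray] = {}

    def evolve(parent_seq: np.ndarray, d: float) -> np.ndarray:
        if d <= 0:
            return parent_seq.copy()
        p_same, p_ts, p_tv = _k2p_transition_probs(d, kappa)
        u = rng.random(length)
        child = parent_seq.copy()
        ts_mask = (u >= p_same) & (u < p_same + p_ts)
        child[ts_mask] = _TS_PARTNER[parent_seq[ts_mask]]
        tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
        tv2 = u >= p_same + p_ts + p_tv
        child[tv1] = _TV_PARTNERS[parent_seq[tv1], 0]
        child[tv2] = _TV_PARTNERS[parent_seq[tv2], 1]
        return child

    node_seqs = {t.seed_node: root_seq}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        d = node.edge.length or 0.0
        node_seqs[node] = evolve(node_seqs[node.parent_node], d)
        if node.is_leaf():
            seqs[node.taxon.label] = node_seqs[node]
    decode = np.array(list("ACGT"))
    return {name: "".join(decode[arr]) for name, arr in seqs.items()}


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_pair(spec: GeneratorSpec, outdir) -> dict:
    """Generate a pair and write GenBank files, tRNA structures and the truth
    table under ``outdir``; returns the truth dict."""
    import json
    from pathlib import Path

    from .io import write_genbank
    from .trna import write_structures

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a, b, truth = generate_pair(spec)
    write_genbank(a, outdir / f"{a.id}.gb")
    write_genbank(b, outdir / f"{b.id}.gb")
    write_structures(truth["structures"], outdir / "trna_structures.txt")
    serializable = {k: v for k, v in truth.items() if k != "structures"}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1, default=str)
    return truth
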