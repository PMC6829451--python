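"""Intron inventory and position-class (Pcl) assignment across two genomes.

Group-I introns are mobile: homologous introns sit at the *same* nucleotide
position of the host coding sequence and retain high sequence similarity. A
position class (Pcl) is therefore keyed by (host gene, insertion coordinate),
where the insertion coordinate is the 1-based count of coding-sequence
nucleotides upstream of the intron ("inserted at 543 nt"). Introns found at
the same coordinate in both genomes form a shared Pcl; an additional pairwise
identity check flags same-position pairs whose sequences have diverged below
the homology threshold (default 70% aligned identity).

cox1 Pcls are conventionally named with letters after a published reference
numbering; supply an exemplar table mapping coordinates to letters to use it,
otherwise provisional ids ``cox1-p<coordinate>`` are emitted. Pcls of other
host genes are numbered by ascending coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_genes import alignment_identity
from .io import AnnotatedMitogenome

HOST_KINDS = ("CDS", "rRNA")  # genes that can carry spliceable introns here


@dataclass
class IntronRecord:
    host: str
    genome_id: str
    coordinate: int       # nt of spliced host sequence preceding the intron
    sequence: str
    group: str = "I"      # e.g. I, IB, ID, novel
    orf_products: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)


def extract_introns(genome: AnnotatedMitogenome) -> list[IntronRecord]:
    """One record per intron, from the exon structure of multi-interval genes.

    The insertion coordinate is the cumulative exon length upstream of the
    intron, measured along the coding strand (so minus-strand genes count
    from the transcription start, not the forward-strand left end).
    """
    from .regions import nested_orfs

    nested = nested_orfs(genome)
    n = len(genome.sequence)
    explicit = genome.features_of_kind("intron")
    records: list[IntronRecord] = []
    for f in genome.features_of_kind(*HOST_KINDS):
        if len(f.intervals) < 2:
            continue
        # exon intervals in transcription order
        exons = list(f.intervals)
        gaps: list[tuple[int, int]] = []  # forward-strand gap intervals
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 <= s2:
                gaps.append((e1, s2))
            elif f.wraps_origin:
                gaps.append((e1, s2 + n))  # wrapped gap; modular arithmetic below
            else:
                raise ValueError(
                    f"genome {genome.id}: inconsistent exon order in {f.name}"
                )
        if f.strand == "-":
            order = list(range(len(exons)))[::-1]
            exon_lens = [exons[i][1] - exons[i][0] for i in order]
            gap_order = list(range(len(gaps)))[::-1]
        else:
            exon_lens = [e - s for s, e in exons]
            gap_order = list(range(len(gaps)))

        upstream = 0
        for k, gi in enumerate(gap_order):
            upstream += exon_lens[k]
            gs, ge = gaps[gi]
            if ge <= n:
                seq = genome.sequence[gs:ge]
            else:
                seq = genome.sequence[gs:] + genome.sequence[: ge - n]
            if f.strand == "-":
                from ._codon import revcomp

                seq = revcomp(seq)
            if not seq:
                raise ValueError(
                    f"genome {genome.id}: zero-length intron in {f.name}"
                )
            group = "I"
            orfs: list[str] = []
            for ex in explicit:
                if ex.start >= gs and ex.end <= min(ge, n):
                    if "group" in ex.product:
                        group = ex.product.split("group")[-1].split()[0]
                    elif ex.product:
                        group = ex.product
            for orf in genome.features_of_kind("ORF"):
                if orf.name in nested and orf.start >= gs and orf.end <= min(ge, n):
                    orfs.append(orf.product or orf.name)
            records.append(
                IntronRecord(
                    host=f.name, genome_id=genome.id, coordinate=upstream,
                    sequence=seq, group=group, orf_products=tuple(orfs),
                )
            )
    return records


@dataclass
class PclAssignment:
    pcl_id: str
    host: str
    coordinate: int
    members: list[IntronRecord] = field(default_factory=list)
    shared: bool = False
    low_similarity: bool = False   # same position but identity < threshold
    identity: float | None = None  # aligned identity of the cross-genome pair
    n_a: int = 0                   # member introns from the first genome
    n_b: int = 0


def assign_pcls(
    introns_a: list[IntronRecord],
    introns_b: list[IntronRecord],
    identity_threshold: float = 0.70,
    cox1_exemplars: dict[int, str] | None = None,
) -> list[PclAssignment]:
    """Group the introns of two genomes into position classes.

    Same-coordinate pairs are additionally checked by global-alignment
    identity; pairs below ``identity_threshold`` keep their shared Pcl but are
    flagged ``low_similarity``.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    genome_a_ids = {r.genome_id for r in introns_a}
    by_pos: dict[tuple[str, int], list[IntronRecord]] = {}
    for rec in list(introns_a) + list(introns_b):
        by_pos.setdefault((rec.host, rec.coordinate), []).append(rec)

    assignments: list[PclAssignment] = []
    counters: dict[str, int] = {}
    for (host, coord) in sorted(by_pos, key=lambda k: (k[0], k[1])):
        members = by_pos[(host, coord)]
        in_a = [m for m in members if m.genome_id in genome_a_ids]
        in_b = [m for m in members if m.genome_id not in genome_a_ids]
        shared = bool(in_a) and bool(in_b)
        identity = None
        low = False
        if shared:
            identity = alignment_identity(in_a[0].sequence, in_b[0].sequence)
            low = identity < identity_threshold
        if host == "cox1":
            if cox1_exemplars and coord in cox1_exemplars:
                pcl_id = cox1_exemplars[coord]
            else:
                pcl_id = f"cox1-p{coord}"
        else:
            counters[host] = counters.get(host, 0) + 1
            pcl_id = f"{host}-{counters[host]}"
        assignments.append(
            PclAssignment(pcl_id=pcl_id, host=host, coordinate=coord,
                          members=members, shared=shared,
                          low_similarity=low, identity=identity,
                          n_a=len(in_a), n_b=len(in_b))
        )
    return assignments


def gain_loss_table(pcls: list[PclAssignment]) -> pd.DataFrame:
    """Per-host-gene tallies of shared vs genome-specific position classes.

    ``fraction_non_homologous`` is the percentage of the gene's Pcls present
    in only one of the two genomes.
    """
    rows: dict[str, dict[str, float]] = {}
    for p in pcls:
        row = rows.setdefault(
            p.host, {"shared": 0, "a_only": 0, "b_only": 0, "total": 0}
        )
        row["total"] += 1
        if p.shared:
            row["shared"] += 1
        elif p.n_a:
            row["a_only"] += 1
        else:
            row["b_only"] += 1
    for row in rows.values():
        unshared = row["a_only"] + row["b_only"]
        row["fraction_non_homologous"] = (
            100.0 * unshared / row["total"] if row["total"] else 0.0
        )
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def intron_inventory(records: list[IntronRecord]) -> pd.DataFrame:
    rows = [
        {"genome": r.genome_id, "host": r.host, "coordinate": r.coordinate,
         "length": r.length, "group": r.group,
         "orf_products": ";".join(r.orf_products)}
        for r in sorted(records, key=lambda r: (r.genome_id, r.host, r.coordinate))
    ]
    return pd.DataFrame(rows)
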