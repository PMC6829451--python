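"""Gene-order collinearity between circular mitogenomes.

Mitochondrial gene order in mushroom-forming fungi is highly rearranged
between genera but can be conserved within one; at gene granularity that is
captured by the signed circular gene order and its breakpoint distance — the
number of gene adjacencies present in one genome but not the other. Orders
are normalized for the arbitrary origin and strand of a circular assembly by
rotating a designated anchor gene (cox1 by default) to the front with '+'
orientation, reflecting the whole order if needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import AnnotatedMitogenome

DEFAULT_SHARED = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3", "nad1", "nad2",
    "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3", "rnl", "rns",
)

SignedGene = tuple[str, int]  # (+1 forward, -1 reverse)


@dataclass(frozen=True)
class GeneOrder:
    genome_id: str
    order: tuple[SignedGene, ...]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.order)


def gene_order(
    genome: AnnotatedMitogenome,
    shared: set[str] | tuple[str, ...] = DEFAULT_SHARED,
    anchor: str = "cox1",
) -> GeneOrder:
    """Signed, rotation/reflection-normalized order of the shared genes."""
    shared = set(shared)
    feats = [
        f for f in genome.features_of_kind("CDS", "rRNA", "ORF")
        if f.name in shared
    ]
    names = [f.name for f in feats]
    dups = {n for n in names if names.count(n) > 1}
    if dups:
        raise ValueError(f"genome {genome.id}: duplicated shared genes {sorted(dups)}")
    order = [(f.name, +1 if f.strand == "+" else -1) for f in feats]
    if not order:
        raise ValueError(f"genome {genome.id}: no shared genes present")
    return GeneOrder(genome_id=genome.id,
                     order=tuple(normalize_order(order, anchor)))


def normalize_order(order: list[SignedGene], anchor: str) -> list[SignedGene]:
    names = [g for g, _ in order]
    if anchor in names:
        i = names.index(anchor)
        if order[i][1] < 0:  # reflect: reverse order and flip all signs
            order = [(g, -s) for g, s in reversed(order)]
            i = [g for g, _ in order].index(anchor)
        order = order[i:] + order[:i]
    return order


def _adjacencies(order: tuple[SignedGene, ...]) -> set[frozenset]:
    """Unordered signed adjacencies of a circular order.

    The adjacency between consecutive signed genes x, y is identified with
    its reading on the other strand (-y, -x), encoded as a canonical pair of
    (gene, side) endpoints: the head of x meets the tail of y.
    """
    adj = set()
    n = len(order)
    for idx in range(n):
        (g1, s1), (g2, s2) = order[idx], order[(idx + 1) % n]
        # endpoint leaving g1 (its head if +, tail if -) touches the endpoint
        # entering g2 (its tail if +, head if -)
        e1 = (g1, "head" if s1 > 0 else "tail")
        e2 = (g2, "tail" if s2 > 0 else "head")
        adj.add(frozenset((e1, e2)))
    return adj


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of circular signed adjacencies of ``a`` absent from ``b``."""
    if a.genes != b.genes:
        raise ValueError("gene orders are over different gene sets")
    return len(_adjacencies(a.order) - _adjacencies(b.order))


def breakpoint_matrix(orders: list[GeneOrder]) -> pd.DataFrame:
    ids = [o.genome_id for o in orders]
    data = [[breakpoint_distance(x, y) for y in orders] for x in orders]
    return pd.DataFrame(data, index=ids, columns=ids)
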