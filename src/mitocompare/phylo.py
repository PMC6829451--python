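"""Concatenated-gene distance phylogeny: supermatrix, NJ, bootstrap, RF.

The combined mitochondrial gene set (15 core protein genes + the two rRNAs)
is concatenated into a partitioned supermatrix; pairwise distances use the
Kimura two-parameter model with pairwise deletion of gap/ambiguous columns,
and trees are built with Saitou & Nei neighbor joining (deterministic
tie-breaking by taxon label, negative branch-length estimates clamped to 0
with a warning). Bootstrap support resamples supermatrix columns with
replacement. This is the desk-scale distance companion to full Bayesian/ML
analyses, which the package exports ready-to-run NEXUS input for instead of
reimplementing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .core_genes import k2p_distance
from .io import CORE_GENES

GENE_ORDER = tuple(CORE_GENES) + ("rnl", "rns")

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]                      # taxon -> concatenated sequence
    partitions: list[tuple[str, int, int]]    # (gene, start, end) half-open
    padded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def array(self) -> np.ndarray:
        """(taxa x columns) uint8 matrix; 4 encodes gap/ambiguity."""
        out = np.full((len(self.taxa), self.width), 4, dtype=np.uint8)
        for i, t in enumerate(self.taxa):
            row = self.rows[t]
            for j, ch in enumerate(row):
                out[i, j] = _ENCODE.get(ch, 4)
        return out


def concatenate(alignments: dict[str, dict[str, str]]) -> Supermatrix:
    """Build a supermatrix from per-gene alignments (gene -> taxon -> row).

    Genes are laid out in canonical order (core genes, rnl, rns, then any
    others alphabetically); a taxon missing from a gene is padded with gaps
    across that partition and recorded in ``padded``.
    """
    for gene, aln in alignments.items():
        if not aln:
            raise ValueError(f"gene {gene}: empty alignment")
        widths = {len(s) for s in aln.values()}
        if len(widths) != 1:
            raise ValueError(f"gene {gene}: rows of unequal length")
        if len(set(aln)) != len(aln):
            raise ValueError(f"gene {gene}: duplicate taxon")
    order = [g for g in GENE_ORDER if g in alignments]
    order += sorted(g for g in alignments if g not in GENE_ORDER)
    taxa = sorted({t for aln in alignments.values() for t in aln})
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    padded: list[tuple[str, str]] = []
    col = 0
    for gene in order:
        aln = alignments[gene]
        width = len(next(iter(aln.values())))
        parts.append((gene, col, col + width))
        for t in taxa:
            if t in aln:
                chunks[t].append(aln[t].upper())
            else:
                chunks[t].append("-" * width)
                padded.append((t, gene))
        col += width
    return Supermatrix(taxa=taxa, rows={t: "".join(c) for t, c in chunks.items()},
                       partitions=parts, padded=padded)


def read_alignment_dir(path) -> dict[str, dict[str, str]]:
    """Read one aligned FASTA per gene (``<gene>.fasta``/``.fa``/``.fna``)."""
    from Bio import SeqIO

    alignments: dict[str, dict[str, str]] = {}
    for p in sorted(Path(path).iterdir()):
        if p.suffix.lower() not in (".fasta", ".fa", ".fna", ".aln"):
            continue
        alignments[p.stem] = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(p), "fasta")
        }
    if not alignments:
        raise ValueError(f"no FASTA alignments found in {path}")
    return alignments


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def k2p_matrix_from_array(arr: np.ndarray, taxa: list[str]) -> np.ndarray:
    """Pairwise K2P distances from an encoded alignment (pairwise deletion)."""
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = arr[i], arr[j]
            ok = (x < 4) & (y < 4)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}"
                )
            diff = ok & (x != y)
            ts = int((diff & ((x ^ y) == 2)).sum())  # purine/pyrimidine pairs
            tv = int(diff.sum()) - ts
            p, q = ts / m, tv / m
            w1, w2 = 1 - 2 * p - q, 1 - 2 * q
            if w1 <= 0 or w2 <= 0:
                raise ValueError("saturated pair in distance matrix")
            dm[i, j] = dm[j, i] = -0.5 * np.log(w1 * np.sqrt(w2))
    return dm


def supermatrix_distances(sm: Supermatrix) -> tuple[list[str], np.ndarray]:
    return sm.taxa, k2p_matrix_from_array(sm.array(), sm.taxa)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(taxa: list[str], matrix: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved by the lexicographically smallest
    pair of cluster labels; negative branch-length estimates are clamped to 0
    with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match taxa")
    if np.isnan(matrix).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")

    clamped = False

    def edge(length: float) -> float:
        nonlocal clamped
        if length < 0:
            clamped = True
            return 0.0
        return length

    # cluster state: newick fragment and label for tie-breaking
    frags = [f"{_quote(t)}" for t in taxa]
    labels = list(taxa)
    dm = matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dm[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                qv = (m - 2) * dm[i][j] - r[i] - r[j]
                key = (qv, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * dm[i][j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dm[i][j] - vi
        vi, vj = edge(vi), edge(vj)
        new_frag = f"({frags[i]}:{vi:.10f},{frags[j]}:{vj:.10f})"
        new_label = min(labels[i], labels[j])
        # distances from the new node
        new_index = len(frags)
        newrow = np.zeros(len(frags) + 1)
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (dm[i][k] + dm[j][k] - dm[i][j])
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[new_index, : len(newrow) - 1] = newrow[:-1]
        dm[: len(newrow) - 1, new_index] = newrow[:-1]
        frags.append(new_frag)
        labels.append(new_label)
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    # three-point formulas for the final star
    li = edge(0.5 * (dm[i][j] + dm[i][k] - dm[j][k]))
    lj = edge(0.5 * (dm[i][j] + dm[j][k] - dm[i][k]))
    lk = edge(0.5 * (dm[i][k] + dm[j][k] - dm[i][j]))
    newick = (f"({frags[i]}:{li:.10f},{frags[j]}:{lj:.10f},"
              f"{frags[k]}:{lk:.10f});")
    if clamped:
        warnings.warn("negative NJ branch length estimate clamped to 0")
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _quote(label: str) -> str:
    return f"'{label}'" if " " in label else label


# ---------------------------------------------------------------------------
# Splits, Robinson-Foulds, bootstrap
# ---------------------------------------------------------------------------


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels.

    Each split is encoded by the side not containing the alphabetically first
    leaf, so the two sides of one bipartition coincide.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    total = len(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= total - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference count of non-trivial splits of two unrooted trees."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(t1) ^ tree_splits(t2))


def bootstrap_support(
    sm: Supermatrix,
    replicates: int = 100,
    seed: int = 0,
    reference: dendropy.Tree | None = None,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Column-resampling bootstrap of the NJ tree.

    Returns the reference tree (built from the full supermatrix unless one is
    supplied) and the percent of replicates containing each of its
    non-trivial splits.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    arr = sm.array()
    taxa = sm.taxa
    if reference is None:
        reference = nj_tree(taxa, k2p_matrix_from_array(arr, taxa))
    ref_splits = tree_splits(reference)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(taxa, k2p_matrix_from_array(arr[:, cols], taxa))
        rep_splits = tree_splits(rep)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}
    return reference, support


def clade_support(support: dict[frozenset, float], clade: set[str]) -> float:
    """Support for a specific clade; 100.0 for trivial clades on 3 taxa."""
    for split, pct in support.items():
        if split == frozenset(clade):
            return pct
    return 0.0


# ---------------------------------------------------------------------------
# Export for external Bayesian/ML runs
# ---------------------------------------------------------------------------


def write_nexus(sm: Supermatrix, path) -> None:
    """NEXUS data matrix plus a charset block per gene partition."""
    with open(str(path), "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.width};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t in sm.taxa:
            fh.write(f"    {t.replace(' ', '_')}  {sm.rows[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, s, e in sm.partitions:
            fh.write(f"  CHARSET {gene} = {s + 1}-{e};\n")
        fh.write("END;\n")
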