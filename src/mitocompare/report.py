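"""End-to-end orchestration of the two-genome comparison.

``run_all`` executes every analysis stage on a pair of annotated mitogenomes
and collects the results into one bundle of data frames; with an output
directory it also writes per-stage TSVs and a Markdown summary. Outputs are
deterministic for a fixed config (the only stochastic stage, bootstrap
support, is seeded). Each summary number comes from exactly one module
result — nothing is recomputed at the report layer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import composition, core_genes, introns, phylo, regions, repeats, synteny, trna
from .io import AnnotatedMitogenome, read_genbank


@dataclass
class PipelineConfig:
    genomes: list  # paths to GenBank files or AnnotatedMitogenome objects
    outdir: str | None = None
    structures: str | dict | None = None   # tRNA dot-bracket sidecar
    alignments: str | dict | None = None   # per-gene alignments for phylogeny
    min_repeat_length: int = 30
    pcl_identity: float = 0.70
    cox1_exemplars: dict[int, str] | None = None
    bootstrap_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pcl_identity <= 1:
            raise ValueError("pcl_identity must be in (0, 1]")
        if self.min_repeat_length < 8:
            raise ValueError("min_repeat_length must be >= 8")


def _load(genome) -> AnnotatedMitogenome:
    if isinstance(genome, AnnotatedMitogenome):
        return genome
    return read_genbank(genome)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of result objects/frames."""
    genomes = [_load(g) for g in config.genomes]
    if len(genomes) < 2:
        raise ValueError("run_all needs at least 2 genomes")
    a, b = genomes[0], genomes[1]
    results: dict = {"genome_ids": [g.id for g in genomes]}
    results["input_digests"] = {
        g.id: hashlib.sha256(g.sequence.encode()).hexdigest()[:16]
        for g in genomes
    }

    # composition + codon usage
    results["composition"] = pd.DataFrame(
        {g.id: composition.composition_stats(g.sequence).as_row()
         for g in genomes}
    ).T
    results["codon_usage"] = {
        g.id: composition.codon_usage(g) for g in genomes
    }
    results["start_stop"] = {
        g.id: composition.start_stop_table(g) for g in genomes
    }

    # regions
    parts = {g.id: regions.partition(g) for g in genomes}
    results["partitions"] = parts
    results["region_table"] = pd.concat(
        {gid: p.as_frame() for gid, p in parts.items()}, names=["genome"]
    )
    results["intergenic"] = {
        gid: regions.intergenic_summary(p) for gid, p in parts.items()
    }
    results["overlaps"] = {gid: p.overlaps for gid, p in parts.items()}
    if len(a.sequence) != len(b.sequence):
        results["expansion"] = regions.expansion_decomposition(
            parts[a.id], parts[b.id])
    else:
        results["expansion"] = None  # equal sizes: decomposition undefined

    # core-gene divergence
    results["divergence"] = core_genes.core_gene_table(a, b)

    # tRNAs
    structures = config.structures
    if isinstance(structures, (str, Path)):
        structures = trna.read_structures(structures)
    results["trna_variation"] = trna.compare_trnas(a, b, structures=structures)

    # introns and position classes
    introns_a = introns.extract_introns(a)
    introns_b = introns.extract_introns(b)
    pcls = introns.assign_pcls(
        introns_a, introns_b, identity_threshold=config.pcl_identity,
        cox1_exemplars=config.cox1_exemplars,
    )
    results["introns"] = {a.id: introns_a, b.id: introns_b}
    results["intron_inventory"] = introns.intron_inventory(
        introns_a + introns_b)
    results["pcls"] = pcls
    results["gain_loss"] = introns.gain_loss_table(pcls)

    # repeats
    results["exact_repeats"] = {
        g.id: repeats.exact_repeats(g.sequence, config.min_repeat_length)
        for g in genomes
    }
    results["tandem_repeats"] = {
        g.id: repeats.tandem_repeats(g.sequence) for g in genomes
    }
    results["tandem_coverage"] = {
        g.id: repeats.tandem_coverage_percent(
            results["tandem_repeats"][g.id], len(g.sequence))
        for g in genomes
    }
    results["similarity_hits"] = {
        g.id: repeats.similarity_hits([g.sequence], [g.sequence])
        for g in genomes
    }

    # gene order
    orders = [synteny.gene_order(g) for g in genomes]
    results["gene_orders"] = orders
    results["breakpoints"] = synteny.breakpoint_matrix(orders)

    # phylogeny (only when per-gene alignments are supplied)
    alignments = config.alignments
    if isinstance(alignments, (str, Path)):
        alignments = phylo.read_alignment_dir(alignments)
    if alignments:
        sm = phylo.concatenate(alignments)
        tree, support = phylo.bootstrap_support(
            sm, replicates=config.bootstrap_replicates, seed=config.seed)
        results["supermatrix"] = sm
        results["tree"] = tree
        results["bootstrap"] = support

    if config.outdir:
        _write_bundle(results, Path(config.outdir))
    return results


def _write_bundle(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = dict(sep="\t")
    results["composition"].to_csv(outdir / "composition.tsv", **tsv)
    results["region_table"].to_csv(outdir / "regions.tsv", **tsv)
    results["divergence"].to_csv(outdir / "divergence.tsv", **tsv)
    results["intron_inventory"].to_csv(outdir / "introns.tsv", **tsv,
                                       index=False)
    results["gain_loss"].to_csv(outdir / "intron_gain_loss.tsv", **tsv)
    results["breakpoints"].to_csv(outdir / "breakpoints.tsv", **tsv)
    for gid, table in results["codon_usage"].items():
        table.as_frame().to_csv(outdir / f"codon_usage.{gid}.tsv", **tsv,
                                index=False)
    results["trna_variation"].as_frame().to_csv(
        outdir / "trna_variation.tsv", **tsv)
    pcl_rows = [
        {"pcl": p.pcl_id, "host": p.host, "coordinate": p.coordinate,
         "shared": p.shared, "identity": p.identity,
         "low_similarity": p.low_similarity, "n_a": p.n_a, "n_b": p.n_b}
        for p in results["pcls"]
    ]
    pd.DataFrame(pcl_rows).to_csv(outdir / "pcls.tsv", **tsv, index=False)
    if "tree" in results:
        results["tree"].write(path=str(outdir / "tree.nwk"), schema="newick")
        phylo.write_nexus(results["supermatrix"], outdir / "supermatrix.nex")
    _write_summary(results, outdir / "summary.md")


def _write_summary(results: dict, path: Path) -> None:
    lines = ["# Mitogenome comparison summary", ""]
    ids = results["genome_ids"]
    lines.append("input digests: " + ", ".join(
        f"{k}={v}" for k, v in results["input_digests"].items()))
    lines.append("")
    lines.append("## Composition")
    lines.append(results["composition"].to_markdown())
    lines.append("")
    lines.append("## Region proportions")
    lines.append(results["region_table"].to_markdown())
    if results.get("expansion") is not None:
        lines.append("")
        lines.append("## Size-expansion decomposition")
        lines.append(results["expansion"].as_frame().to_markdown())
    elif results.get("expansion") is None and len(ids) >= 2:
        lines.append("")
        lines.append("expansion decomposition: N/A (equal genome sizes)")
    lines.append("")
    lines.append("## Core-gene divergence")
    lines.append(results["divergence"].round(4).to_markdown())
    lines.append("")
    lines.append("## Intron gain/loss by host gene")
    lines.append(results["gain_loss"].to_markdown())
    lines.append("")
    tv = results["trna_variation"]
    lines.append(f"tRNAs with variable sites: {tv.n_variable_trnas}; "
                 f"domain totals: {tv.domain_totals}")
    lines.append("")
    lines.append("## Breakpoint distances")
    lines.append(results["breakpoints"].to_markdown())
    path.write_text("\n".join(lines) + "\n")
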