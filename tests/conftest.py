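import warnings

import numpy as np
import pytest

from mitocompare import AnnotatedMitogenome, GeneFeature, GeneratorSpec, generate_pair

SEED = 11


@pytest.fixture(scope="session")
def pair():
    """The default synthetic study pair (genome a, genome b, truth tables)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_pair(GeneratorSpec(seed=SEED))


@pytest.fixture(scope="session")
def pipeline_results(pair, tmp_path_factory):
    """Full run_all output on GenBank files written from the study pair."""
    from mitocompare import PipelineConfig, run_all, write_genbank

    a, b, truth = pair
    d = tmp_path_factory.mktemp("genomes")
    write_genbank(a, d / "a.gb")
    write_genbank(b, d / "b.gb")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(PipelineConfig(
            genomes=[str(d / "a.gb"), str(d / "b.gb")],
            cox1_exemplars=truth["cox1_exemplars"],
            seed=SEED,
        ))


def make_genome(sequence, features=(), genome_id="toy", circular=True):
    return AnnotatedMitogenome(id=genome_id, sequence=sequence,
                               circular=circular, features=list(features))


def feat(name, kind, intervals, strand="+", **kw):
    return GeneFeature(name=name, kind=kind,
                       intervals=tuple(tuple(iv) for iv in intervals),
                       strand=strand, **kw)


def random_annotated_genome(rng: np.random.Generator) -> AnnotatedMitogenome:
    """A small genome with arbitrary (possibly overlapping) annotation, for
    conservation-type property checks."""
    n = int(rng.integers(1500, 6000))
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    kinds = ["CDS", "tRNA", "rRNA", "ORF", "intron"]
    features = []
    for i in range(int(rng.integers(0, 12))):
        kind = kinds[int(rng.integers(len(kinds)))]
        start = int(rng.integers(0, n - 120))
        if kind == "CDS" and rng.random() < 0.4:  # two-exon gene
            e1 = start + int(rng.integers(30, 60))
            s2 = e1 + int(rng.integers(10, 40))
            e2 = min(n, s2 + int(rng.integers(30, 60)))
            if s2 >= e2:
                continue
            intervals = [(start, e1), (s2, e2)]
        else:
            intervals = [(start, start + int(rng.integers(40, 120)))]
        strand = "+" if rng.random() < 0.7 else "-"
        features.append(feat(f"g{i}_{kind}", kind, intervals, strand))
    return make_genome(seq, features, genome_id=f"rand{rng.integers(1 << 30)}")
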