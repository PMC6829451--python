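"""Reading/writing annotated mitogenomes and the package-wide coordinate rules.

Conventions used by every other module:

* Coordinates are 0-based, half-open, on the forward strand. Report-level
  output converts to 1-based inclusive (GenBank style).
* A feature is a list of intervals stored in 5'->3' order *along the forward
  strand* (ascending starts), so minus-strand coding sequences are obtained by
  concatenating the intervals and reverse-complementing once.
* Features spanning the origin of a circular genome keep two intervals in
  transcription order, e.g. ``[(60000, 66704), (0, 412)]``, and are flagged
  with :attr:`GeneFeature.wraps_origin`; length arithmetic treats them as
  contiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._codon import revcomp

CORE_GENES = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "rps3",
)

FEATURE_KINDS = ("CDS", "intron", "tRNA", "rRNA", "ORF")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature: a gene symbol plus its genomic footprint."""

    name: str
    kind: str  # one of FEATURE_KINDS
    intervals: tuple[tuple[int, int], ...]
    strand: str = "+"  # '+' or '-'
    product: str = ""
    anticodon: str | None = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name}: empty interval list")
        for s, e in self.intervals:
            if not s < e:
                raise ValueError(f"feature {self.name}: bad interval ({s}, {e})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: strand must be '+' or '-'")
        if not self.wraps_origin:
            prev_end = None
            for s, e in self.intervals:
                if prev_end is not None and s < prev_end:
                    raise ValueError(
                        f"feature {self.name}: intervals unsorted or overlapping"
                    )
                prev_end = e

    @property
    def length(self) -> int:
        """Summed interval length (spliced length for multi-exon features)."""
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


@dataclass
class AnnotatedMitogenome:
    """A (usually circular) mitochondrial genome with typed features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: non-ACGTN characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if e > n:
                    raise ValueError(
                        f"genome {self.id}: feature {f.name} interval ({s}, {e}) "
                        f"exceeds sequence length {n}"
                    )
        seen_core: set[str] = set()
        for f in self.features:
            if f.kind == "CDS" and f.name in CORE_GENES:
                if f.name in seen_core:
                    raise ValueError(
                        f"genome {self.id}: core gene {f.name} annotated twice as CDS"
                    )
                seen_core.add(f.name)

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedMitogenome):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and self.circular == other.circular
            and sorted(self.features, key=_feature_key)
            == sorted(other.features, key=_feature_key)
        )

    # --- lookups -------------------------------------------------------

    def features_of_kind(self, *kinds: str) -> list[GeneFeature]:
        out = [f for f in self.features if f.kind in kinds]
        return sorted(out, key=_feature_key)

    def get_cds(self, gene: str) -> GeneFeature:
        """The CDS (or standalone ORF) feature for ``gene``."""
        for f in self.features:
            if f.name == gene and f.kind in ("CDS", "ORF", "rRNA"):
                return f
        raise KeyError(f"genome {self.id}: no CDS/ORF/rRNA feature named {gene!r}")

    def core_cds(self) -> dict[str, GeneFeature]:
        return {
            f.name: f
            for f in self.features
            if f.kind == "CDS" and f.name in CORE_GENES
        }

    def extract(self, feature: GeneFeature) -> str:
        """Spliced sequence of a feature, reverse-complemented for strand '-'."""
        parts = [self.sequence[s:e] for s, e in feature.intervals]
        seq = "".join(parts)
        return revcomp(seq) if feature.strand == "-" else seq


def _feature_key(f: GeneFeature):
    return (f.start, f.end, f.kind, f.name)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"CDS": "CDS", "ORF": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "intron": "intron"}
_GB_TO_KIND = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "intron": "intron"}


def read_genbank(path) -> AnnotatedMitogenome:
    """Parse a GenBank flat file into an :class:`AnnotatedMitogenome`.

    ``join()``/``complement()`` locations are mapped onto the internal 0-based
    half-open convention; CDS features named ``orf*`` are tagged ``kind=ORF``
    (intron-nested hypothetical ORFs are annotated that way by fungal
    mitogenome pipelines).
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # re-raise with the offending file named
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: record has no ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") == "circular"
    n = len(seq)

    features: list[GeneFeature] = []
    for sf in record.features:
        if sf.type not in _GB_TO_KIND:
            continue
        name = _feature_name(sf)
        kind = _GB_TO_KIND[sf.type]
        if kind == "CDS" and name.lower().startswith("orf"):
            kind = "ORF"
        strand = "-" if sf.location.strand == -1 else "+"
        intervals = [(int(p.start), int(p.end)) for p in sf.location.parts]
        wraps = False
        if len(intervals) > 1:
            in_order = all(
                intervals[i][0] <= intervals[i + 1][0]
                for i in range(len(intervals) - 1)
            )
            if not in_order:
                # minus-strand joins arrive in transcription order
                # (descending); flip them to the forward-strand convention
                flipped = intervals[::-1]
                if strand == "-" and all(
                    flipped[i][1] <= flipped[i + 1][0]
                    for i in range(len(flipped) - 1)
                ):
                    intervals = flipped
                elif circular:
                    # genuinely out-of-order join on a circular genome:
                    # the feature spans the origin; keep the given order
                    wraps = True
                else:
                    intervals = sorted(intervals)
        anticodon = None
        if "anticodon" in sf.qualifiers:
            anticodon = str(sf.qualifiers["anticodon"][0]).strip("()").lower()[-3:]
        product = str(sf.qualifiers.get("product", [""])[0])
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                intervals=tuple(intervals),
                strand=strand,
                product=product,
                anticodon=anticodon,
                wraps_origin=wraps,
            )
        )
    genome = AnnotatedMitogenome(
        id=record.id or record.name, sequence=seq, circular=circular,
        features=features,
    )
    _warn_on_frame(genome)
    return genome


def _feature_name(sf: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return f"{sf.type}_{int(sf.location.start)}"


def _warn_on_frame(genome: AnnotatedMitogenome) -> None:
    for f in genome.features:
        if f.kind == "CDS" and f.length % 3 != 0:
            warnings.warn(
                f"genome {genome.id}: CDS {f.name} length {f.length} not a "
                "multiple of 3; codon-level statistics drop the partial codon",
                stacklevel=3,
            )


def write_genbank(genome: AnnotatedMitogenome, path) -> None:
    """Write a genome so that ``read_genbank`` recovers it exactly."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.replace(" ", "_")[:16] or "mitogenome",
        description=f"{genome.id} mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in sorted(genome.features, key=_feature_key):
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.product:
            quals["product"] = [f.product]
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind],
                                          qualifiers=quals))
    with open(str(path), "w") as fh:
        SeqIO.write(record, fh, "genbank")


# ---------------------------------------------------------------------------
# Sequence access and circular arithmetic
# ---------------------------------------------------------------------------


def coding_sequence(genome: AnnotatedMitogenome, gene: str) -> str:
    """Spliced coding sequence of ``gene`` in transcription order.

    Exon intervals are concatenated along the forward strand and the result
    reverse-complemented once for minus-strand genes; intron gaps between
    intervals are excluded.
    """
    return genome.extract(genome.get_cds(gene))


def rotate(genome: AnnotatedMitogenome, offset: int) -> AnnotatedMitogenome:
    """Shift the origin of a circular genome by ``offset`` bases.

    Features that end up straddling the new origin get the two-interval
    wrapped representation. Used mainly to check rotation invariance of the
    downstream statistics.
    """
    if not genome.circular:
        raise ValueError("rotate() requires a circular genome")
    n = len(genome.sequence)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    new_features = []
    for f in genome.features:
        intervals: list[tuple[int, int]] = []
        wraps = False
        for s, e in f.intervals:
            ns = (s - offset) % n
            ne = ns + (e - s)
            if ne <= n:
                intervals.append((ns, ne))
            else:
                intervals.extend([(ns, n), (0, ne - n)])
                wraps = True
        if not wraps and any(
            intervals[i][0] > intervals[i + 1][0] for i in range(len(intervals) - 1)
        ):
            wraps = True  # multi-exon feature now spans the origin
        new_features.append(replace(f, intervals=tuple(intervals),
                                    wraps_origin=wraps))
    return AnnotatedMitogenome(id=genome.id, sequence=seq,
                               circular=True, features=new_features)
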