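# Methods

This note documents the models, conventions, defaults, and limitations of
`mitocompare`, in the order the pipeline runs them.

## Coordinates and annotation model

All internal coordinates are 0-based half-open on the forward strand; report
output converts to 1-based inclusive (GenBank convention). A feature stores
its intervals in 5'→3' order along the forward strand, so a minus-strand
coding sequence is one concatenation plus one reverse complement. Features
that span the origin of a circular genome keep two (or more) intervals in
transcription order with a `wraps_origin` flag; length arithmetic treats
them as contiguous. Minus-strand `complement(join(...))` locations arrive
from GenBank parsers in transcription (descending) order and are flipped to
the forward convention on read; a join that is out of order *after* that
flip on a circular genome is interpreted as origin-spanning.

A CDS whose length is not divisible by 3 raises a warning, not an error —
annotation pipelines occasionally emit these — and codon-level statistics
drop the trailing partial codon. CDS features named `orf*` are typed as
hypothetical ORFs; an ORF wholly contained in an intron is "nested" and is
treated as intronic cargo, not as protein-coding sequence.

## Composition and codon usage

Skew denominators of zero return a skew of 0 with a warning so whole-genome
tables stay total. N bases are excluded from every composition denominator.
Report rounding is 2 decimals for percentages and skews. Codon usage pools
the 15 core protein-coding genes by default (a per-gene breakdown is also
kept); whether hypothetical ORFs should be included is genuinely open for
real annotations, so the gene set is a parameter. Translation uses NCBI
genetic code 4 throughout (TGA = tryptophan; only TAA/TAG terminate).

## Region partition and expansion decomposition

Each base receives exactly one label with priority protein-coding > RNA >
intronic > intergenic. Per-base labelling is the only convention under which
category totals provably sum to the genome length when genes overlap, which
in turn makes the expansion decomposition close at exactly 100% before
rounding. Intron-nested ORFs count as intronic: treating them as coding
would move several kilobases between categories and break the
interpretation of the intronic fraction as "intron turnover". Gene overlaps
are reported as positive base counts per feature pair (display layers may
sign them negative, matching the field's "(−85 bp)" convention). Intergenic
spans wrap the origin on circular genomes. The decomposition is undefined
for equal-size genomes and raises instead of dividing by zero.

## Divergence statistics

**K2P** uses pairwise deletion of gap/N columns. Arguments `(1−2P−Q) ≤ 0`
or `(1−2Q) ≤ 0` raise a saturation error rather than producing NaN.

**NG86 Ka/Ks** follows the counting method a DnaSP-style workflow computes,
with one documented refinement: mutational pathways passing through a stop
codon are excluded from the equal-weight pathway average (if every pathway
hits a stop — possible only for 2–3-step changes — all pathways are used so
the codon pair still contributes its full difference count). This choice
changes third-decimal results and is therefore pinned by an exhaustive
enumeration test over all 62² code-4 sense-codon pairs. Site counting
treats stop-creating changes as nonsynonymous so synonymous + nonsynonymous
sites equal 3 per codon. Ka/Ks with Ks = 0 is reported as NA, never ∞. Note
the Jukes–Cantor correction saturates at p = 3/4, so a *single* codon pair
with one synonymous difference is already saturated; meaningful Ks needs a
run of codons.

Unequal-length genes are globally aligned (match +1 / mismatch −1 / gap −2)
before K2P, and codon-aware aligned (protein alignment back-mapped to
codons) before Ka/Ks; only columns with codons in both sequences enter the
counts.

## tRNAs

Matching is by isoacceptor identity (amino acid + anticodon); isodecoders
are paired by genome order — arbitrary but deterministic. Domain labels come
from a dot-bracket secondary-structure sidecar when supplied (the three
hairpins in 5'→3' order are the D, anticodon and T arms; outer pairs are the
acceptor stem; the unpaired stretch between anticodon and T arms is the
variable region). Without a structure, a canonical position template
(7 bp acceptor stem, 4+8+4 D arm, 5+7+5 anticodon arm, variable region,
5+7+5 T arm, discriminator) is used, which keeps the statistic reproducible
at the cost of ignoring noncanonical folds. Gene lengths outside 71–88 bp
draw a warning. Equal-length pairs are compared positionally; unequal pairs
are globally aligned first with positions reported in first-genome
coordinates.

## Intron position classes

The insertion coordinate is the count of host coding-sequence nucleotides
upstream of the intron ("inserted at 543 nt"), measured along the coding
strand, with exact coordinate equality required for co-classification
(±0 nt): "same position" is taken literally, which is also what makes the
classes a partition. The homology identity threshold defaults to 0.70 over
the global alignment of the paired intron sequences; same-position pairs
below it keep their class but are flagged `low_similarity`. Lettered cox1
class names require an external exemplar table (coordinate → letter);
otherwise provisional `cox1-p<coordinate>` ids are used, and non-cox1 hosts
are numbered by ascending coordinate. Group I/II subtypes (IB, ID, novel)
are read from annotation, not predicted. Gain/loss fractions use position
classes as the denominator (a shared class counts once), which is the
convention under which "1 unshared of 7" reads as 14.29%.

## Repeats

*Exact repeats* enumerates all maximal exact pairs ≥ `min_length`
(default 30, hard floor 8) in four orientations — forward, reverse
(reversed, not complemented), complemented, and palindromic (reverse
complemented) — by seeding on exact words and extending to maximality; an
exhaustive all-diagonals scan serves as the test oracle.

*Tandem repeats* anchors on an exact periodic stretch of at least
max(8, period/2) matching positions, then extends by X-drop scoring
(match +2, mismatch −8, drop 30), which tolerates ~20% interior unit
mismatches while refusing to absorb flanking random sequence; harmonic
periods overlapping a smaller-period call ≥80% are suppressed. Units below
11 bp are not reported by default. Decayed arrays with no exact anchor are
missed — a stated sensitivity limit of the detector.

*Interspersed/similarity hits* seed on 11-mers, extend ungapped with
X-drop, then rescore locally, on both strands; significance uses the
Karlin–Altschul E-value `E = K·m·n·e^(−λS)` with ungapped +1/−2 DNA
constants λ = 1.3328, K = 0.621 and database length = total subject length,
cut at E < 10⁻¹⁰. Self-scans drop identical-locus diagonal hits and report
each symmetric pair once. The same operation scanned against synthetic
nuclear contigs finds NUMT-style transferred fragments; genome-scale
nuclear scans are out of scope.

## Gene order and phylogeny

Gene orders are signed circular sequences over the shared set (default:
15 core genes + rnl + rns), normalized by rotating the anchor (cox1) to the
front with + orientation, reflecting if necessary. The breakpoint distance
counts adjacencies of one order absent from the other, identifying each
adjacency with its opposite-strand reading; it is verified to be a metric by
sampling. Nucleotide-level collinear blocks and rearrangement-scenario
inference (reversal/DCJ distances) are out of scope: the biological claim —
order conserved within the pair, scrambled across the class — lives at gene
granularity.

The phylogeny stage concatenates per-gene alignments in canonical order
with gap-padding for missing taxa, computes K2P distances with pairwise
deletion, and runs Saitou–Nei neighbor joining with ties broken by
lexicographic cluster label and negative branch estimates clamped to 0 with
a warning. Bootstrap resamples supermatrix columns with replacement;
support is the replicate frequency of each reference-tree split. Bayesian
and maximum-likelihood tree searches are deliberately not reimplemented —
the module exports a ready-to-run NEXUS matrix with charset partitions for
external tools, and NJ + bootstrap carries the desk-scale topology checks.

## The synthetic generator

The generator is the package's ground-truth instrument: it emulates the
empirical structure of a two-species fungal mitogenome comparison and
records every planted quantity. Defaults (one choice, not revisited):

* sizes exactly 66,704 and 77,109 bp; base probabilities A .375, C .100,
  G .115, T .410 → ~78.5% AT, negative AT skew, positive GC skew;
* 15 core genes with realistic lengths, ATG/TAA codons except a TTG start
  on cox1 and a TAG stop on cob; three genes (nad3, nad4, rps3) shortened
  by 7/2/20 codons in the sister genome;
* 25 cloverleaf tRNAs built on the canonical structure template (two
  serine/arginine/leucine isoacceptors, three methionine isodecoders; long
  variable arms on Ser/Leu), so domain maps are exact by construction;
* 16 vs 24 group-I introns in a plan that yields non-homologous fractions
  of 14.29% (cob), 50% (cox3), 60% (nad5) and 100% (rnl), a private cox2
  intron at 543 nt, shared introns at 97% identity, and intronic
  LAGLIDADG/GIY-YIG ORFs; intron lengths are set so the expansion
  decomposition lands at +134.3% intronic / −29.1% coding / −5.2%
  intergenic of the 10,405 bp difference;
* per-gene K2P substitution rates 0.004–0.08 with third-position weighting
  emulating purifying selection (rps3 least weighted → fastest and most
  nonsynonymous; atp8 restricted to synonymous transitions → Ka = 0);
  κ = 2 throughout;
* planted repeats in the larger genome: an 810 bp duplicate at 95%
  identity, tandem arrays of 12 bp × 13 and 29 bp × 4, a 50 bp exact
  forward pair and a 40 bp palindromic pair (guard bases stop accidental
  maximal extension), plus one 20 bp × 3 array in the smaller genome;
* an 85 bp overlap between cox3 and the downstream hypothetical ORF;
  identical gene order in both genomes; intergenic spans including forced
  37 bp minimum and 1791 bp maximum spacers, with the remainder sized to
  hit the genome targets exactly;
* a 5-taxon tree with the two focal genomes as sisters for supermatrix
  simulation.

Substitutions that would create an in-frame stop are re-targeted to another
base — a mild, documented departure from a free K2P process that keeps the
annotations valid. Sequence evolution along trees uses the exact K2P
transition probabilities per branch, so distance estimators are consistent
against planted branch lengths.

What the generator does **not** emulate: mutation-rate heterogeneity along
genes, indels inside alignments (length variation enters only as whole-codon
deletions), realistic intron secondary structure, base-composition
heterogeneity between regions, and sequencing/annotation error. Passing
tests therefore demonstrate correctness of the statistics and bookkeeping on
clean annotations, not robustness to noisy real-world annotation.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on the
66.7/77.1 kb pair (a few seconds), exhaustive codon-pair enumeration
(62² pairs), 200 random sequences for the repeat-scan oracle, 100 random
additive matrices for NJ, 100 random annotated genomes for conservation
checks, and 100 bootstrap replicates on a 10 kb five-taxon supermatrix —
sizes chosen so every oracle can be exhaustive or tightly bounded while the
whole suite stays fast. All randomness flows from explicit seeds; rerunning
any stage with the same inputs and seed is byte-identical.

## Known limitations

* The K2P/NG86 implementations assume reasonably low divergence; saturated
  inputs raise errors rather than extrapolating.
* The tandem detector needs an exact periodic anchor (see above).
* cox1 letter naming is only as good as the supplied exemplar table.
* The heuristic tRNA domain template misassigns positions for noncanonical
  cloverleaves; supply dot-bracket structures for those.
* Isodecoder pairing by genome order can mispair copies across genomes with
  rearranged tRNA clusters; with conserved order (the case here) it is
  exact.
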