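# Methods

## Variant model and normalization

A variant record is one normalized germline call: chromosome (1–22, X, Y),
1-based position, single reference and alternate allele, gene, transcript,
consequence class, Phred quality, VAF, optional scaled CADD score, and a
map of per-cohort allele frequencies. Multi-allelic VCF rows are decomposed
at read time (an n-allelic row yields n − 1 records). Normalization trims
shared trailing then leading bases (keeping at least one base per allele)
and, when a reference-context callback is supplied, left-aligns indels by
the standard shift-left rule; it is idempotent, and identity across
individuals is the normalized (chrom, pos, ref, alt) tuple.

VAF is taken from a FORMAT `AF` field when present, otherwise computed as
alt depth / total depth from `AD`; a call with zero total depth is dropped
with a warning rather than guessed at.

Consequence vocabulary: LoF = {nonsense, frameshift, essential_splice},
plus missense and other. "Essential splice" is taken as ±2 bp of an exon
boundary (the canonical donor/acceptor dinucleotides); the source material
names the class without defining a width, so the standard width is adopted
as an explicit assumption.

When a gene has several transcript annotations for one variant, the record
carried forward is the most deleterious under the fixed order
nonsense = frameshift = essential_splice > missense > other, with ties
broken by preferring curated RefSeq accessions (`NM_` prefix) and then the
lexicographically smallest accession. Only the relative order of the broad
classes is documented upstream, so the rank table is a configurable
argument rather than a constant.

## Filter cascade

Stage order: per-individual quality/heterozygosity (quality strictly > 30,
VAF in [0.15, 0.8] inclusive, class LoF or missense) → per-individual
novelty against the discovery cohorts (presence/absence: any record of the
allele excludes, because the discovery panels are used as "seen before"
filters, not frequency resources) → sharing between the two individuals →
curation blacklist → deleteriousness (LoF free pass; missense needs scaled
CADD ≥ 10; missense *lacking* a score is excluded with a warning, the
conservative choice) → rarity in the verification cohort (excluded iff
frequency strictly exceeds 1 × 10⁻⁴; absence means frequency 0). The
blacklist precedes the CADD stage because read-level curation happened
before deleteriousness scoring in the workflow this models.

Boundary semantics are deliberate and configurable: strict `>` for
quality, inclusive band for VAF, inclusive `≥` for CADD, strict `>` for
the frequency exclusion. The per-step ledger (per-individual counts plus
total/LoF/missense splits for the shared stages) is a first-class output
because the survivor trajectory is itself evidence.

Each stage is a pure predicate, so per-stage results are invariant under
input permutation and the CADD and frequency stages commute; both
properties are asserted in the test suite.

## Segment algebra

Segments are 0-based half-open internally. The SEG dialect (1-based
inclusive start) is shifted on read; BED passes through; the plain table
dialect is declared half-open. Event vocabulary: LOH, CN_LOSS,
CN_LOSS_LOH, CN_GAIN, parsed case-insensitively from labels such as
"CN Loss/LOH".

The bundled per-tumour segment tables are encoded exactly as printed and
declared 0-based half-open — several rows start at 0, which makes that
reading the natural one; at megabase scale the one-coordinate ambiguity is
immaterial to every conclusion drawn. The run-together published text of
the first tumour's table is resolved so that its first row is
chromosome 1, 0–26,948,921: the only reading consistent with exactly one
LOH region being common to both tumours (a chromosome-10 reading would
manufacture a second overlap).

The LOH-bearing view keeps LOH and CN_LOSS_LOH always, and pure CN_LOSS
only on request: a hemizygous deletion does imply loss of one allele, but
array exports label it separately, so cross-tumour LOH intersection
excludes it by default while the two-hit overlay includes it by default
(a deletion over the variant is the strongest second hit). Normalization
merges overlapping and book-ended same-event segments; intersection is a
per-chromosome sweep over event-agnostic merged intervals, dropping
zero-length results; genome fraction is merged union length divided by the
genome model's total length, with out-of-range segments an error. Lengths
are reported in Mb rounded half-away-from-zero to two decimals
(1,771,307 bp → 1.77 Mb).

The published tumour genome-LOH percentages are *not* asserted anywhere:
their denominator (whole genome vs array-covered territory) is not
recoverable, so the genome-fraction operation is validated against
per-base bitmap oracles instead.

## Two-hit overlay

A candidate's 1-based position is converted to 0-based and tested for
half-open containment; an indel is "in" a segment iff its start position
is, since segments are six-plus orders of magnitude larger. Zones:
`shared_loh` (inside the cross-tumour intersection), `loh_in_one` (inside
exactly one tumour's view, sample recorded), `none` (including
chromosomes absent from the segment tables — absence of array data is not
an error). Allele observations map to status (mutant_only →
mutant_retained_wt_lost, wildtype_only → mutant_lost, both →
heterozygous_retained, missing → unobserved). Candidacy: `contradicted`
iff the mutant allele was lost; `supported` iff in an LOH zone with only
the mutant retained; everything else `unresolved` — in particular,
observed heterozygosity inside an LOH zone, which can reflect subclonal
heterogeneity or sequencing of a different tumour site than the array, is
classified, never rejected. No formal decision rule for "supported" exists
upstream; the rule here is the minimal formalization of the two-hit
reasoning and is documented as such.

## Synthetic duo generator

The generator plants variants by fate: a category that survives every
filter, and one category per filter planted to fail exactly it, plus two
per-individual backgrounds (private novel calls that die at the sharing
step, and cohort-member calls that die at the novelty step). Annotation
values are drawn uniformly from ranges that stay clear of every filter
boundary (e.g. passing VAF in [0.25, 0.70], failing frequency in
[5 × 10⁻⁴, 2 × 10⁻²]); a `boundary_stress` flag pins values exactly on the
boundaries for stress testing, while ordinary boundary semantics are
covered by dedicated unit tests. Positions are placed on a toy genome
(GRCh37 chromosome lengths scaled by 1/1000, so per-base oracles stay
cheap), inside or outside planted LOH territory per the in-LOH quota;
placement draws are rejected until unique, with exhaustion an error.

The default configuration is study-shaped: planted counts chosen so the
cascade yields, by construction, ~4.9k heterozygous coding calls per
individual, 106/110 after novelty, 40 shared (8 LoF / 32 missense), 31
after curation, 24 after CADD, 15 final (1 LoF / 14 missense), 4 of them
in LOH private to the first tumour; the tumour segment tables are the
published ones scaled to the toy genome. This is an emulation of the
study's count skeleton, not a reproduction of its data: the generator
does not simulate reads, realistic site-frequency spectra, linkage,
annotation error, or tumour purity, so exact recovery on synthetic duos
demonstrates the pipeline's bookkeeping and boundary logic, not its
robustness to noisy real-world annotation.

Determinism: one `numpy` generator seeded from the config drives every
draw; outputs are written in sorted order without timestamps, so a seed
reproduces the bundle byte-for-byte. VCFs encode VAF as allele depths at
depth 100, so a round-trip preserves variant keys exactly and VAF to
within 0.01 — draws avoid filter boundaries by more than that margin.

## Verification strategy and problem sizes

Interval operations (intersection, union length, genome fraction, point
containment) are checked against per-base boolean bitmaps on toy genomes —
1000 random instances on a ~12 kb three-chromosome genome — and the
cascade against planted truth on several seeds plus the study-shaped
configuration (~10k variant records per duo). These sizes keep the full
suite under a minute while leaving the algebra oracle-verified at a
density (dozens of overlapping segments per kb-scale chromosome) far
harsher than real array exports.

## Known limitations

- Candidate genomic coordinates in `duohit.datasets` are synthetic
  placements at each gene's GRCh37 locus (the publication identifies
  variants by transcript and cDNA change only); containment conclusions
  are insensitive to the intra-gene offset, but the exact positions should
  not be quoted.
- The cascade models sharing between exactly two individuals; no
  segregation model, phasing, or de novo logic.
- Cohort panels are exact-key lookups; no fuzzy matching across
  normalization conventions beyond the package's own normalizer.
- The two-hit overlay ignores tumour purity and subclonal structure; a
  `both alleles` observation inside LOH is deliberately left unresolved.
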