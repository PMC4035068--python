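# Methods

## Coordinate model

All input and reported coordinates are GFF3-style 1-based inclusive
(BED exports are 0-based half-open). The TSS of a stranded interval is
its 5′-most coordinate: `start` on the forward strand, `end` on the
reverse strand. Gene spans are recomputed as the union of member
transcripts rather than trusted from the gene line, because the
gene-level search model is defined on "gene cluster" boundaries — the
5′-most and 3′-most extents over all transcripts.

GFF3 is parsed line-by-line with gffutils' feature parser rather than
through a gffutils database: this keeps line numbers available for
error messages (orphan transcripts, inverted coordinates, duplicate
IDs) and gives the package full control over hierarchy validation,
while the column/attribute syntax is still handled by the established
parser. Transcript feature types are an allowlist (mRNA, transcript,
the common ncRNA classes, pseudogenic_transcript) because annotation
dialects disagree; biotypes come from `biotype`/`gene_biotype`/`type`
attributes, else are inferred from the feature type (pseudogene,
transposable_element_gene), else default to protein_coding, and can be
overridden from a two-column TSV. `cds_start` is derived from CDS
children (5′-most CDS base in transcript orientation) when present.

A gene whose transcripts disagree on strand is accepted with a warning
rather than rejected: such records occur as annotation errors in real
files, and the pair searches' same-gene filter is the correct place to
neutralize them. Chromosome disagreement is still an error. FASTA
loading (Biopython) uppercases sequence, rejects non-IUPAC characters,
and stores IUPAC ambiguity codes as N so that downstream composition
statistics see a clean {A,C,G,T,N} alphabet. Chromosomes annotated but
missing from the FASTA are kept for pair searching (coordinates
suffice) and excluded, with a warning, from sequence analyses.

## Pair geometry and the gap rule

All four pair geometries share one piece of interval arithmetic: for a
left member ending at *L* and a right member starting at *R* on the
same chromosome with non-overlapping bodies, the two compared anchors
are the facing ends (both TSSs for head-to-head, both 3′ ends for
convergent, 3′→5′ for co-directional) and the gap is *R* − *L* − 1,
the number of bases strictly between the anchors. "Less than 1.0 kb"
is implemented as gap ∈ [1, 999]; abutting (gap 0) and overlapping
candidates are excluded. This strictly-between convention reproduces
the canonical worked case: a reverse gene ending at 500 facing a
forward gene starting at 1136 has a 635-bp promoter.

**Gene level (nearest neighbour).** Two genes pair only when no third
gene's span intersects the open interval between their spans. On
well-formed annotations this is exactly adjacency in coordinate order,
but unlike raw sort-order adjacency it is symmetric under coordinate
translation and chromosome reverse-complement even when gene spans are
nested — a property the test suite checks — and it is insensitive to
sort tie-breaking. The sweep implementation uses a prefix-maximum of
span ends over position-sorted genes; an independent O(n²) brute-force
oracle applies the predicates literally and must agree on every input.

**Transcript level (all pairs).** Every transcript is tested against
every opposite-strand (or same-strand, for co-directional) transcript
within range, with no nearest-neighbour restriction — this is what
lets alternative TSSs rescue pairs hidden by overlapping long
transcripts, and what creates *redundant* members (a transcript in
more than one pair). Pairs of transcripts belonging to one gene are
excluded: a gene cannot be its own partner. Pairs whose gap contains a
third transcript's TSS are *not* excluded, but the count of such
intervening TSSs is recorded per pair (`n_intervening`) so users can
filter. Pair output order and pair ids are deterministic functions of
(chrom, anchors, member ids).

**Accounting.** For a set of *P* pairs, the 2*P* member slots decompose
into unique members and redundant re-occurrences, so
unique = 2*P* − redundant always; unique transcript members translate
to their distinct parent genes, and comparison against a baseline pair
set (typically gene-level vs transcript-level) reports the genes gained
by the transcript-level model. Pair categories are assigned from member
biotypes: coding–coding, coding–pseudogene, coding–transposable-element,
else "other".

## Promoter analysis

**TATA windows.** The −10…−50 region upstream of each TSS is
interpreted per promoter end: a motif hits the right end when it starts
(5′→3′, forward strand) 10–50 bp inward from the right edge, and the
left end when it starts 10–50 bp inward from the left edge on the
reverse complement. Scanning the reverse complement with the same
windowed routine makes the classification exactly symmetric under
reverse-complementing the promoter with end labels swapped. Windows
truncate automatically at the boundaries of promoters shorter than the
far offset. The four strict motifs include one 6-mer (`TTATTT`) and
three 7-mers; the set and window bounds are parameters. A promoter is
classified `both_ends` / `one_end` (exactly one) / `none`; the
at-least-one-end percentage is also reported since "one end" is
ambiguous in common usage.

**Composition.** GC content is pooled over all bases of the set (N
excluded from numerator and denominator), which weights promoters by
length; the unweighted per-region mean is emitted alongside because
published tables rarely state which convention they use. All-N regions
are dropped from composition with a warning.

**Random-promoter background.** Each of 20 replicates samples 1000
genes uniformly without replacement (with replacement, logged, when
fewer exist) and takes the region immediately upstream — strand-aware
— of the gene's anchor: the start-codon position when a CDS is
annotated, else the first transcript's TSS ("first" = smallest
transcript id, for determinism). The region length defaults to the
observed mean promoter length rounded to an integer (440 bp is the
classic maize value). Per replicate the pooled GC and the fraction of
regions with a TATA motif in the single TSS-proximal −10…−50 window
(scanned in gene orientation, one strand — a polar promoter has one
TSS) are computed; the summary is the mean over replicates. All
sampling derives from one seed and is bit-reproducible.

**De-duplication.** Alternative transcripts of one gene pair generate
nested promoters differing only at their ends. Within each unordered
gene-pair group, promoters are sorted by length; the shortest is kept
and each longer one only if it exceeds the last kept length by ≥ 50 bp
(greedy), so `{200, 230, 300}` keeps `{200, 300}`.

**Distributions.** Length histograms use fixed 100-bp bins
[k·100, (k+1)·100) with a range accessor (e.g. the share of promoters
100–300 bp); per-chromosome summaries report counts, percentages, and
the top-k aggregate share.

## Ortholog conservation

BLASTp tabular input (outfmt 6, 12 columns) is filtered at
e-value < 1e−10 (strict, matching the usual reporting convention).
The query→subject map keeps one best hit per query — smallest e-value,
then largest bitscore, then lexicographically smallest subject id — so
the map is independent of hit-file line order; reciprocal-best-hit
filtering was considered and left out of the default because a single
ortholog count per species is the quantity of interest, but self-hits
can be excluded for within-species searches. A source pair counts as
conserved at threshold *t* when both members map, the two subjects lie
on one target chromosome on opposite strands in divergent orientation
(reverse-strand TSS strictly left of forward-strand TSS), and the
absolute TSS difference is ≤ *t*. The TSS difference (not gap − 1) is
used because conservation thresholds span kilobases, where the
one-base distinction is immaterial and the absolute difference is the
natural distance. Thresholds (default 0.5/1/2/5 kb) are cumulative, so
counts are non-decreasing — an invariant the tests assert. Both
members mapping to the same subject is not a pair. Shared-ortholog
analysis reports exclusive Venn regions (ids mapped in exactly a given
subset of 2–4 species), which partition the union.

## Synthetic data

The generator emulates the *layout* of a gene-dense genomic
neighbourhood, not gene biology: single-transcript two-gene cassettes
of each geometry at controlled gaps, multi-transcript cassettes (two
reverse-strand transcripts sharing a 3′ end, the longer one overlapping
the forward neighbour by 150 bp so only the transcript-level model can
see the pair), and isolated decoys, separated by 1001–2000 bp spacers
so no unplanned sub-kilobase pair can arise. A post-generation audit
re-runs all eight search configurations and fails loudly if the found
pairs differ from the planted truth, making the truth table exact
rather than probabilistic. Background sequence is i.i.d. from a
configurable base composition; planted TATA motifs are written at
exact window offsets and the surrounding window sequence is resampled
until the scan classification equals the plan, so AT-rich compositions
cannot corrupt the planted classes. Defaults (uniform base
composition, gaps uniform on part of [1, 999], gene bodies 300–800 bp)
are what the tests run; real genomes differ in ways the generator does
not model — introns/UTRs, clustered gene families, compositional
heterogeneity, incomplete annotations — so passing tests demonstrate
correctness of the computations, not biological performance.

The ortholog fixture maps every source-pair member to a planted target
transcript: a chosen fraction of pairs become divergent target pairs at
planned TSS distances, the rest are scattered across chromosomes or
onto one strand; the emitted BLAST table carries the true map at
1e−30, weaker passing secondary hits (to exercise best-hit selection),
and decoy hits at 1e−5 (to exercise the filter).

## Problem sizes

The bundled verification runs use deliberately moderate sizes — a few
hundred genes per synthetic genome, 200 random annotations of ≤ ~120
transcripts for the oracle equivalence sweep, 50 cassette pairs in the
acceptance pipeline — chosen so the whole suite completes in seconds
while every code path (both levels, all four geometries, planted and
adversarial inputs) is exercised. The implementations themselves are
O(n log n + pairs) sweeps and scale to full genome annotations.

## Known limitations

Overlapping and nested gene architectures are deliberately excluded
from pairing (non-overlap is part of the pair definition here);
operons, exon structure beyond the optional CDS start, liftover, and
de novo motif discovery are out of scope. Whether published
transcript-pair counts de-duplicated multi-transcript combinations of
one gene pair is not generally stated; this package keeps all
qualifying transcript pairs and offers the 50-bp promoter rule as the
explicit collapsing step.
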