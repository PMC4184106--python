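# Methods

## Data model

A variant's identity is `(chrom, pos, ref, alt)` with 1-based inclusive
coordinates throughout.  Indels use the `-` notation of the exome
annotation ecosystem: pure insertions have `ref == "-"` (position = the
base after which the sequence is inserted), pure deletions `alt == "-"`
(position = first deleted base).  VCF's anchored representation is reduced
to this form at the input boundary by stripping the maximal common
prefix, then the maximal common suffix, of REF/ALT and left-aligning the
remaining event against the REF allele string.  No reference genome is
consulted; left-alignment is therefore exact within the record's own
context, which is sufficient for identity of calls produced from the same
reference.  Normalization is idempotent (property-tested).  Chromosome
names are stored verbatim.

Summary-table identity is `(chrom, pos, alt)`, mirroring how a
multi-allelic site yields one row per alternative allele; `ref` is carried
for validation and two imports disagreeing on `ref` at the same key are a
hard error.  Carrier sets live in a normalized link table
`(variant_id, sample_id, zygosity)` with a cached `n_carriers` on the
summary row; this gives the same one-lookup filtering contract as packing
carrier lists into the row, but with integrity that a full-scan audit can
check mechanically (`audit_check`, run after every mutation in the
tests).

## Import semantics

Each sample import is one transaction: parse → per-sample call tables →
summary fold-in.  A variant never seen before is annotated (exactly once
over the store's lifetime — verified by an invocation counter in the
tests) and inserted; a known variant only has its carrier set extended.
Removal reverses this and deletes summary rows whose carrier set becomes
empty, making `remove(add(S))` an exact inverse (byte-identical audit
dumps) and imports order-independent.  Batch import skips existing sample
ids with a notice and quarantines failing samples without aborting the
batch.

## Annotation

Region classification per transcript: exonic (within the CDS span),
UTR5/UTR3 (exonic outside the CDS, oriented by strand), splicing
(intronic within `splice_window` bases of an exon–intron junction),
intronic, upstream/downstream (within 1 kb outside the transcript,
oriented by strand), ncRNA (exonic in a model with no CDS), else
intergenic.  Across transcripts the highest-precedence class wins:
`exonic = splicing > ncRNA > UTR5 = UTR3 > intronic > upstream =
downstream > intergenic`, with deterministic (gene, transcript)
tie-breaking.  Choices that the class vocabulary leaves open and that are
pinned by tests:

- `splice_window` defaults to 2 bp — the canonical donor/acceptor
  dinucleotide — and is configurable.
- An exonic position that is also within the window of a junction reports
  *exonic* (with its coding effect); *splicing* is reserved for
  intronic-side positions.
- The window rule applies to noncoding models' introns as well; their
  exonic positions report ncRNA.
- Indels are classified by their first affected base.

Coding effects: SNVs are translated with the standard genetic code
(reference vs alternate codon; same amino acid → synonymous, gain of stop
→ stopgain, loss of stop → stoploss, else nonsynonymous).  Exonic indels
are frameshift iff the net inserted-minus-deleted length is not a multiple
of 3.  With overlapping transcripts the most severe effect is reported
(stopgain > stoploss > frameshift > nonsynonymous > nonframeshift >
synonymous) — deterministic and clinically conservative.

Instead of a reference genome, each coding model carries its spliced CDS
sequence (coding orientation) in an extra refFlat column; that sequence is
authoritative for reference codons.  dbSNP membership (rs-id + a
common-variant flag) and per-variant scores (SIFT, PolyPhen2, PhyloP,
LRT, MutationTaster, GERP) come from exact-key lookup TSVs; score tables
cover SNVs only.

## Filtering

Thresholds are integer-safe: "at least X%" of *n* means
`count ≥ ceil(X·n)`, "at most Y%" of *m* means `count ≤ floor(Y·m)`, both
computed with a 1e-9 epsilon guard against binary-float artifacts
(`0.1 × 30` is not exactly 3 in floating point).  This makes `X = 1`
mean "all" and `Y = 0` mean "none" exactly.  An empty filter-group is
legal and vacuously passes; an empty in-group is rejected.  The
`hom_in_group` constraint requires every in-group carrier of a candidate
to be homozygous.  Output ordering is (natural chromosome order,
position, alt), so result files are diffable.

The central correctness property — the summary-table filter is
*identical* to exhaustive enumeration over all variants and all groups —
is tested on ≥1000 randomized (store, spec) trials, with annotations
supplied by a dict-backed test annotator so class and dbSNP predicates are
exercised against known truth.  The scaling claim is stated
hardware-independently and tested as a countable property: per-sample
tables opened by the summary-table path is ≤ |in-group| at every size of
a 10→200-sample series, while the naive baseline's table touches grow
strictly with the cohort.  Wall-clock comparisons on any particular
hardware are deliberately out of scope.

## Synthetic cohorts

`generate_cohort` realizes planted truths exactly: per-population
frequencies by deterministic rounding (`round(f·n)` carriers, taken as
the first k of a seed-fixed shuffle), explicit carrier lists verbatim.
This makes scenario tests equality assertions, not statistical ones.
Background structure is a shared pool (default 20 variants, each carried
by a random subset of up to half the cohort, ~20% hom) plus at most one
private het variant per sample (rate 0.5) — enough to exercise carrier
arithmetic without modelling mutation rates, LD, kinship or read-level
error, none of which affect what the filter engine computes from carrier
sets.  Passing tests therefore demonstrate the filtering semantics and
warehouse consistency, not calling accuracy on real data.

The scenario presets plant one true variant each (de novo in a trio child;
dominant het across three affected; recessive hom in two affected with
het relatives in the discard-group; population-specific at 20% vs 0%
screened at the 10%/1% thresholds) alongside decoys that violate exactly
one condition (partial in-group carriage, a filter-group carrier, a het
where hom is required, or a sub-threshold frequency).

### The worked example

`build_wdm_fixture` reconstructs the dominant-myopathy screen at desk
scale: samples P1 and P2 carry the 13 published candidate SNPs (all
heterozygous) and two indel candidates; ≥20 control samples carry decoys
violating one condition each (carried by two controls; dbSNP-common;
carried by only one affected; private to a control).  One candidate is
deliberately given a single control carrier to exercise the "at most one
filter-group carrier" boundary.  Toy gene models are built so that
annotation reproduces the published classes and gene symbols exactly:
single-exon genes placing each nonsynonymous locus at CDS offset 4
(GCT→GTT, Ala→Val; one gene on the minus strand to exercise
reverse-complement handling), two-exon genes whose introns contain the
intronic loci, and a two-exon gene carrying both a deep-intronic and a
synonymous (GCT→GCA) locus.  The published table lists no alleles,
depths or qualities; the fixture's values (e.g. het 14/11, q92) are
documented inventions.  The screen itself applies only the published
conditions — full in-group carriage, at most one control carrier, and
dbSNP-common exclusion (the published candidate list itself contains
rs-id-bearing, intronic and synonymous rows, so no damaging-class
constraint and no blanket dbSNP exclusion can have been applied; the
fixture flags the candidates' rs-ids as non-common accordingly).  A
damaging-class constraint (`DAMAGING_CLASSES`) is available and tested
separately.

## Numerical and degenerate-input choices

- Depth fallback on VCF import: AD when present, else `DP-1/1`, else a
  `0/1` placeholder with a logged warning (a call implies ≥1 supporting
  read, so `alt_depth` is clamped to ≥1).
- Half-calls (`./1`) are rejected; phased separators are accepted and
  mapped to het/hom by allele counts; `0/0` and `./.` records are
  skipped; symbolic ALTs are skipped with a warning.
- Duplicate calls for one variant within one sample file keep the first
  occurrence (warned).
- A coding SNV whose ref allele contradicts the model's CDS base raises
  in strict mode; the store-side annotator uses non-strict mode (CDS base
  authoritative, debug-logged) so arbitrary cohorts can be annotated
  against toy fixtures.

## Problem sizes used by the test and acceptance runs

Randomized-equivalence trials use stores of ≤8 samples and ≤50 variants
(1000 trials); the consistency soak runs 100 add/remove operations with a
full audit after each; the scaling series tops out at 200 samples × ~10
variants each; the worked example uses 26 samples.  These sizes keep the
whole suite in the tens of seconds while the properties they check are
size-independent by construction.

## Known limitations

- No reference-genome validation, gVCF/BCF/BAM input, phasing, HGVS
  nomenclature, or structural variants; batch VCFs must be split before
  import.
- Left-alignment without a genome cannot cross the boundaries of the VCF
  record's own REF string.
- No association statistics: the engine filters by carrier counts, it
  does not test hypotheses; LD and kinship are out of scope.
- Single-user embedded store; no access control, replication or schema
  migration.
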