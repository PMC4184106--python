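# varvault

A local, embedded warehouse for SNP and indel calls from many resequencing
samples, with a group-based filtering engine whose cost does not grow with
the number of samples in the database.

## The problem

Screening for candidate disease-causing mutations in exome or genome
resequencing cohorts means asking questions like: *which variants are
carried by every affected individual but (almost) no control?* or *which
variants are common in one population but rare everywhere else?*  Doing
this with per-sample files and successive filtering steps is slow and
error-prone, and it gets worse every time a sample is added.

varvault stores each sample's calls in per-sample tables inside one SQLite
database and maintains two **denormalized summary tables** (one for SNPs,
one for indels): one row per distinct variant `(chrom, pos, alt)` holding
the set of carrier samples, the dbSNP rs-id, the functional class
(nonsynonymous, frameshift, splicing, ...) and per-variant scores.  The
summary tables are updated on every import or removal, so any group-based
filtering is an indexed lookup over them.

## The filtering model

Samples are partitioned into three groups: the **in-group** (must carry
the variant), the **filter-group** (negative controls) and the
**discard-group** (ignored).  A variant *v* with carrier set *C(v)* passes
when

```
|C(v) ∩ in|     ≥ ⌈X · |in|⌉          and
|C(v) ∩ filter| ≤ ⌊Y · |filter|⌋      (or an absolute count T)
```

with optional conjunctive constraints: functional-class membership, dbSNP
exclusion (all entries or common-flagged only), and in-group homozygosity
(for recessive designs).  Frequencies are per *carrier individual*, not
per allele.  Special cases fall out naturally: `X=1` means "all affected",
`Y=0` or `T=0` means "no control" (the de novo / trio design), and
fractional thresholds on two populations give cohort-differential screens.

Candidate selection runs entirely against the summary and carrier tables;
per-sample tables are touched only to attach genotype details to the
surviving variants, so at most `|in-group|` of them are opened regardless
of cohort size.  A deliberately naive baseline (`naive_filter`: join two
per-sample tables, then loop over every other sample) is included; its
table touches grow linearly with the cohort and it doubles as an
independent correctness oracle in the tests.

## Worked example

The package ships a generator for the worked example that drove the
design: a screen for an autosomal-dominant distal myopathy mutation using
two affected, unrelated exomes against a background cohort.  Both affected
samples carry the 13 published candidate SNPs (loci, rs-ids, classes and
gene symbols as published; alleles and read depths are fixture values);
the control samples carry decoys that each violate exactly one filter
condition.

```python
import tempfile
from varvault.synthdata import build_wdm_fixture
from varvault.filter_engine import group_filter, result_to_tsv

with tempfile.TemporaryDirectory() as d:
    fx = build_wdm_fixture(d)
    result = group_filter(fx.store, fx.spec)
    print(len(result))
    print(result_to_tsv(result))
```

prints `13` and a table whose first lines are

```
Pos	Rsid	Class	Gene	Ref	Alt	InCarriers	FilterCarriers	GT:P1	GT:P2
chr1:16535487	rs143314517	Nonsynonymous	ARHGEF19	C	T	2	0	het(14/11,q92)	het(14/11,q92)
chr2:69049697	rs199643431	Nonsynonymous	ARHGAP25	G	A	2	0	het(14/11,q92)	het(14/11,q92)
chr2:70439862		Nonsynonymous	TIA1	C	T	2	0	het(14/11,q92)	het(14/11,q92)
...
```

Exactly two candidates are nonsynonymous variants on chromosome 2 — in
*ARHGAP25* and *TIA1*, the linkage region of the disorder (the *TIA1*
variant was the experimentally confirmed cause).  Running the same
grouping against the indel summary table returns the 2 indel candidates.

The same pipeline is available from the shell:

```
varvault init store.db
varvault import --store store.db --gene-models gene_models.tsv \
    --dbsnp dbsnp.tsv --scores scores.tsv samples.tsv
varvault filter --store store.db --in-sample P1 --in-sample P2 \
    --max-filter-count 1 --exclude-dbsnp common_only --out result.tsv
```

Other subcommands: `stats` (per-sample and global counts), `remove`,
`region` (per-population carrier-frequency / MAF tables over an interval),
and `simulate` (synthetic cohorts with planted de novo, dominant,
recessive or population-specific variants and known truth).

## Layout

- `varvault.io_formats` — domain types and all file I/O: internal variant
  TSV, single-sample VCF (with indel normalization to `-` notation),
  sample sheets, refFlat/genePred gene models.
- `varvault.datastore` — the warehouse: per-sample tables, summary and
  carrier tables, batch import, removal, audits.
- `varvault.annotate` — region and coding-effect classification, dbSNP and
  score lookups.
- `varvault.filter_engine` — the group filter, the naive baseline, the
  population screen, cost instrumentation.
- `varvault.synthdata` — synthetic cohorts and fixtures with planted
  truth.
- `varvault.cli_reports` — the CLI, config round-trips, region/MAF and
  stats reports.

See `docs/methods.md` for the underlying model, parameter choices and
limitations.
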