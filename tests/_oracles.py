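"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration / per-base
scanning, without touching the summary tables, the SQL filter path, or the
interval logic of the annotator they check.
"""

from __future__ import annotations

import math
import random

from varvault.annotate import AnnotationResult
from varvault.datastore import add_sample_calls, init_store
from varvault.io_formats import GenotypeCall, VariantKey


def oracle_min_count(fraction: float, n: int) -> int:
    return math.ceil(fraction * n - 1e-9)


def oracle_max_count(fraction: float, n: int) -> int:
    return math.floor(fraction * n + 1e-9)


class DictAnnotator:
    """Test annotator backed by a plain dict: key -> AnnotationResult."""

    def __init__(self, table=None):
        self.table = dict(table or {})
        self.n_calls = 0

    def annotate(self, variant):
        self.n_calls += 1
        return self.table.get(
            variant, AnnotationResult("intergenic", "none", "")
        )


def oracle_group_filter(truth, annotations, spec):
    """Exhaustive enumeration over every variant any sample carries.

    ``truth``: dict sample_id -> {VariantKey: zygosity};
    ``annotations``: dict VariantKey -> AnnotationResult (default
    intergenic/none).  Returns the set of passing VariantKeys.
    """
    default = AnnotationResult("intergenic", "none", "")
    all_keys = set()
    for per in truth.values():
        all_keys.update(per)
    wanted_kind = spec.variant_table
    need_in = oracle_min_count(spec.min_in_fraction, len(spec.in_group))
    if spec.max_filter_count is not None:
        max_f = spec.max_filter_count
    else:
        max_f = oracle_max_count(
            spec.max_filter_fraction, len(spec.filter_group)
        )
    passing = set()
    for key in all_keys:
        if key.kind != wanted_kind:
            continue
        ann = annotations.get(key, default)
        if spec.class_constraint is not None and (
            ann.region_class, ann.effect_class
        ) not in spec.class_constraint:
            continue
        if spec.exclude_dbsnp == "all" and ann.rsid:
            continue
        if spec.exclude_dbsnp == "common_only" and ann.is_dbsnp_common:
            continue
        in_carriers = [
            sid for sid in spec.in_group if key in truth.get(sid, {})
        ]
        if len(in_carriers) < need_in:
            continue
        if spec.zygosity_constraint == "hom_in_group" and any(
            truth[sid][key] != "hom" for sid in in_carriers
        ):
            continue
        f_count = sum(
            1 for sid in spec.filter_group if key in truth.get(sid, {})
        )
        if f_count > max_f:
            continue
        passing.add(key)
    return passing


def random_truth_and_annotations(rng: random.Random, max_samples=8,
                                 max_variants=50):
    """A random tiny cohort: ground-truth carrier map + random annotations."""
    n_samples = rng.randint(2, max_samples)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    n_variants = rng.randint(1, max_variants)
    keys = []
    for j in range(n_variants):
        chrom = rng.choice(["chr1", "chr2", "chr10", "chrX"])
        pos = 1000 + 13 * j
        if rng.random() < 0.25:  # indel
            if rng.random() < 0.5:
                key = VariantKey(chrom, pos, "-", "AT")
            else:
                key = VariantKey(chrom, pos, "TG", "-")
        else:
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            key = VariantKey(chrom, pos, ref, alt)
        keys.append(key)
    truth = {sid: {} for sid in sample_ids}
    for key in keys:
        carriers = rng.sample(sample_ids, rng.randint(1, n_samples))
        for sid in carriers:
            truth[sid][key] = rng.choice(["het", "het", "hom"])
    regions = ["exonic", "splicing", "intronic", "intergenic", "UTR5"]
    annotations = {}
    for key in keys:
        region = rng.choice(regions)
        if region == "exonic":
            effect = rng.choice(
                ["nonsynonymous", "synonymous", "stopgain", "frameshift"]
            )
        else:
            effect = "none"
        rsid = f"rs{rng.randint(1, 10**6)}" if rng.random() < 0.4 else ""
        common = bool(rsid) and rng.random() < 0.5
        annotations[key] = AnnotationResult(
            region, effect, "G1" if region != "intergenic" else "", rsid,
            common,
        )
    return truth, annotations


def build_store_from_truth(truth, annotations):
    """Materialize a ground-truth carrier map as an in-memory store."""
    store = init_store(":memory:")
    annotator = DictAnnotator(annotations)
    for sid in sorted(truth):
        snps, indels = [], []
        for key, zyg in sorted(truth[sid].items(), key=lambda kz: kz[0].sort_key()):
            call = GenotypeCall(key, zyg, 10, 5, 50.0)
            (snps if key.is_snp else indels).append(call)
        add_sample_calls(store, sid, snps, indels, annotator)
    return store


def random_spec(rng: random.Random, sample_ids, variant_table=None):
    """A random valid FilterSpec partitioning ``sample_ids``."""
    from varvault.filter_engine import FilterSpec

    ids = list(sample_ids)
    rng.shuffle(ids)
    n_in = rng.randint(1, max(1, len(ids) - 1))
    in_group = ids[:n_in]
    rest = ids[n_in:]
    n_discard = rng.randint(0, len(rest))
    discard = rest[:n_discard]
    filt = rest[n_discard:]
    kwargs = dict(
        in_group=frozenset(in_group),
        discard_group=frozenset(discard),
        filter_group=frozenset(filt),
        min_in_fraction=rng.choice([0.0, 0.25, 0.5, 0.75, 1.0, rng.random()]),
        variant_table=variant_table or rng.choice(["snp", "indel"]),
        exclude_dbsnp=rng.choice(["off", "all", "common_only"]),
        zygosity_constraint=rng.choice(["any", "any", "hom_in_group"]),
    )
    if rng.random() < 0.5:
        kwargs["max_filter_count"] = rng.randint(0, max(0, len(filt)))
    else:
        kwargs["max_filter_fraction"] = rng.choice(
            [0.0, 0.01, 0.1, 0.5, 1.0, rng.random()]
        )
    if rng.random() < 0.4:
        pool = [
            ("exonic", "nonsynonymous"),
            ("exonic", "synonymous"),
            ("exonic", "stopgain"),
            ("exonic", "frameshift"),
            ("splicing", "none"),
            ("intronic", "none"),
        ]
        kwargs["class_constraint"] = frozenset(
            rng.sample(pool, rng.randint(1, len(pool)))
        )
    return FilterSpec(**kwargs)


# ---------------------------------------------------------------------------
# per-base region-classification oracle
# ---------------------------------------------------------------------------

_REGION_RANK = {
    "exonic": 0,
    "splicing": 0,
    "ncRNA": 1,
    "UTR5": 2,
    "UTR3": 2,
    "intronic": 3,
    "upstream": 4,
    "downstream": 4,
    "intergenic": 5,
}


def paint_model(model, splice_window=2):
    """Per-base class map for one transcript, built by painting arrays."""
    lo = model.tx_start - 1000
    hi = model.tx_end + 1000
    classes = {}
    for p in range(lo, model.tx_start):
        classes[p] = "upstream" if model.strand == "+" else "downstream"
    for p in range(model.tx_end + 1, hi + 1):
        classes[p] = "downstream" if model.strand == "+" else "upstream"
    for p in range(model.tx_start, model.tx_end + 1):
        classes[p] = "intronic"
    exonic_positions = set()
    for s, e in zip(model.exon_starts, model.exon_ends):
        for p in range(s, e + 1):
            exonic_positions.add(p)
    # splice window: intronic bases near a junction
    for s, e in zip(model.exon_starts, model.exon_ends):
        for d in range(1, splice_window + 1):
            for p in (s - d, e + d):
                if (
                    model.tx_start <= p <= model.tx_end
                    and p not in exonic_positions
                ):
                    classes[p] = "splicing"
    for p in exonic_positions:
        if model.cds_start is None:
            classes[p] = "ncRNA"
        elif model.cds_start <= p <= model.cds_end:
            classes[p] = "exonic"
        elif p < model.cds_start:
            classes[p] = "UTR5" if model.strand == "+" else "UTR3"
        else:
            classes[p] = "UTR3" if model.strand == "+" else "UTR5"
    return classes


def oracle_classify(pos, chrom, models, splice_window=2):
    """Best class across transcripts by per-base painting + precedence."""
    best = ("intergenic", "")
    best_rank = (_REGION_RANK["intergenic"], "", "")
    found = False
    for model in models:
        if model.chrom != chrom:
            continue
        classes = paint_model(model, splice_window)
        if pos not in classes:
            continue
        cls = classes[pos]
        rank = (_REGION_RANK[cls], model.gene_symbol, model.transcript_id)
        if not found or rank < best_rank:
            best = (cls, model.gene_symbol)
            best_rank = rank
            found = True
    return best
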