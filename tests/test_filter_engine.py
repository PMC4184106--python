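"""Group filter semantics, the naive baseline, counters, and monotonicity."""

import random

import pytest

from _oracles import (
    DictAnnotator,
    build_store_from_truth,
    oracle_group_filter,
    random_spec,
    random_truth_and_annotations,
)
from varvault.annotate import AnnotationResult
from varvault.datastore import add_sample_calls, init_store
from varvault.errors import UnsupportedInputError, ValidationError
from varvault.filter_engine import (
    DAMAGING_CLASSES,
    FilterSpec,
    filter_cost_counters,
    group_filter,
    max_carriers_allowed,
    min_carriers_required,
    naive_filter,
    population_filter,
    result_to_tsv,
)
from varvault.io_formats import GenotypeCall, VariantKey


def _call(key, zyg="het"):
    return GenotypeCall(key, zyg, 12, 8, 55.0)


def _trio_store():
    """child carries a private variant and one inherited from the mother."""
    store = init_store(":memory:")
    de_novo = VariantKey("chr1", 100, "A", "G")
    inherited = VariantKey("chr1", 200, "C", "T")
    add_sample_calls(store, "child", [_call(de_novo), _call(inherited)])
    add_sample_calls(store, "mother", [_call(inherited)])
    add_sample_calls(store, "father", [_call(VariantKey("chr1", 300, "G", "A"))])
    return store, de_novo, inherited


# ---------------------------------------------------------------------------
# threshold arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "frac, n, expected",
    [(1.0, 5, 5), (0.0, 5, 0), (0.5, 5, 3), (0.1, 30, 3), (0.34, 3, 2)],
)
def test_min_carriers_ceiling(frac, n, expected):
    assert min_carriers_required(frac, n) == expected


@pytest.mark.parametrize(
    "frac, n, expected",
    [(0.0, 10, 0), (1.0, 10, 10), (0.01, 100, 1), (0.3, 10, 3), (0.05, 30, 1)],
)
def test_max_carriers_floor(frac, n, expected):
    assert max_carriers_allowed(frac, n) == expected


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

def test_spec_validation_errors():
    store, *_ = _trio_store()
    samples = store.sample_ids()
    with pytest.raises(ValidationError, match="non-empty"):
        FilterSpec(in_group=frozenset(),
                   filter_group=frozenset(samples),
                   max_filter_count=0).validate(samples)
    with pytest.raises(ValidationError, match="disjoint"):
        FilterSpec(in_group=frozenset(["child"]),
                   filter_group=frozenset(samples),
                   max_filter_count=0).validate(samples)
    with pytest.raises(ValidationError, match="partition"):
        FilterSpec(in_group=frozenset(["child"]),
                   filter_group=frozenset(["mother"]),
                   max_filter_count=0).validate(samples)
    with pytest.raises(ValidationError, match="exactly one"):
        FilterSpec(in_group=frozenset(["child"]),
                   filter_group=frozenset(["mother", "father"]),
                   max_filter_count=0, max_filter_fraction=0.0
                   ).validate(samples)
    # validation happens before any table access
    with pytest.raises(ValidationError):
        group_filter(store, FilterSpec(in_group=frozenset(["ghost"]),
                                       max_filter_count=0))


# ---------------------------------------------------------------------------
# worked semantics
# ---------------------------------------------------------------------------

def test_de_novo_boundary():
    """Y=0: a variant private to the child passes, an inherited one fails."""
    store, de_novo, inherited = _trio_store()
    spec = FilterSpec(
        in_group=frozenset(["child"]),
        filter_group=frozenset(["mother", "father"]),
        min_in_fraction=1.0,
        max_filter_count=0,
    )
    result = group_filter(store, spec)
    assert result.keys() == {de_novo}
    hit = result.hits[0]
    assert hit.in_carrier_count == 1 and hit.filter_carrier_count == 0
    assert hit.genotypes["child"].variant == de_novo


def test_empty_filter_group_is_vacuous():
    store = init_store(":memory:")
    key = VariantKey("chr1", 100, "A", "G")
    add_sample_calls(store, "only", [_call(key)])
    spec = FilterSpec(in_group=frozenset(["only"]), max_filter_fraction=0.0)
    assert group_filter(store, spec).keys() == {key}


def test_discard_group_is_ignored():
    store, de_novo, inherited = _trio_store()
    spec = FilterSpec(
        in_group=frozenset(["child"]),
        discard_group=frozenset(["mother"]),
        filter_group=frozenset(["father"]),
        min_in_fraction=1.0,
        max_filter_count=0,
    )
    # with the mother discarded, the inherited variant passes too
    assert group_filter(store, spec).keys() == {de_novo, inherited}


def test_hom_in_group_constraint():
    store = init_store(":memory:")
    hom_key = VariantKey("chr1", 100, "A", "G")
    het_key = VariantKey("chr1", 200, "C", "T")
    add_sample_calls(store, "A1", [_call(hom_key, "hom"), _call(het_key)])
    add_sample_calls(store, "A2", [_call(hom_key, "hom"), _call(het_key)])
    add_sample_calls(store, "C1", [])
    spec = FilterSpec(
        in_group=frozenset(["A1", "A2"]),
        filter_group=frozenset(["C1"]),
        max_filter_count=0,
        zygosity_constraint="hom_in_group",
    )
    assert group_filter(store, spec).keys() == {hom_key}


def test_class_constraint_and_dbsnp_exclusion():
    ann_table = {
        VariantKey("chr1", 100, "A", "G"): AnnotationResult(
            "exonic", "nonsynonymous", "G1"),
        VariantKey("chr1", 200, "C", "T"): AnnotationResult(
            "exonic", "synonymous", "G1"),
        VariantKey("chr1", 300, "G", "A"): AnnotationResult(
            "exonic", "nonsynonymous", "G1", "rs1", True),
        VariantKey("chr1", 400, "T", "C"): AnnotationResult(
            "exonic", "nonsynonymous", "G1", "rs2", False),
    }
    store = init_store(":memory:")
    annotator = DictAnnotator(ann_table)
    add_sample_calls(store, "S1", [_call(k) for k in ann_table], annotator=annotator)
    spec = FilterSpec(
        in_group=frozenset(["S1"]),
        max_filter_count=0,
        class_constraint=DAMAGING_CLASSES,
        exclude_dbsnp="common_only",
    )
    # synonymous decoy dropped by the class constraint, dbSNP-common by the
    # common-only exclusion; the rare rs2 variant survives
    assert group_filter(store, spec).keys() == {
        VariantKey("chr1", 100, "A", "G"),
        VariantKey("chr1", 400, "T", "C"),
    }
    spec_all = FilterSpec(
        in_group=frozenset(["S1"]),
        max_filter_count=0,
        class_constraint=DAMAGING_CLASSES,
        exclude_dbsnp="all",
    )
    assert group_filter(store, spec_all).keys() == {
        VariantKey("chr1", 100, "A", "G"),
    }


def test_result_ordering_and_tsv():
    store = init_store(":memory:")
    keys = [
        VariantKey("chr10", 5, "A", "G"),
        VariantKey("chr2", 7, "C", "T"),
        VariantKey("chr2", 7, "C", "A"),
        VariantKey("chr1", 9, "G", "A"),
    ]
    add_sample_calls(store, "S1", [_call(k) for k in keys])
    spec = FilterSpec(in_group=frozenset(["S1"]), max_filter_count=0)
    result = group_filter(store, spec)
    ordered = [h.summary.variant for h in result]
    assert ordered == [
        VariantKey("chr1", 9, "G", "A"),
        VariantKey("chr2", 7, "C", "A"),
        VariantKey("chr2", 7, "C", "T"),
        VariantKey("chr10", 5, "A", "G"),
    ]
    tsv = result_to_tsv(result)
    lines = tsv.strip().split("\n")
    assert lines[0].startswith("Pos\tRsid\tClass\tGene")
    assert len(lines) == 5
    assert lines[1].startswith("chr1:9")


# ---------------------------------------------------------------------------
# brute-force oracle equivalence (the module's central property)
# ---------------------------------------------------------------------------

def test_group_filter_matches_bruteforce_enumeration():
    """Randomized stores and specs; the long 1000-trial run is in the
    acceptance suite."""
    rng = random.Random(20140201)
    for trial in range(30):
        truth, annotations = random_truth_and_annotations(rng)
        store = build_store_from_truth(truth, annotations)
        for _ in range(5):
            spec = random_spec(rng, truth.keys())
            got = group_filter(store, spec).keys()
            expected = oracle_group_filter(truth, annotations, spec)
            assert got == expected, f"trial {trial} spec {spec}"
        store.close()


def test_monotonicity_in_thresholds():
    rng = random.Random(42)
    truth, annotations = random_truth_and_annotations(rng)
    store = build_store_from_truth(truth, annotations)
    ids = sorted(truth)
    in_group = frozenset(ids[:2])
    rest = frozenset(ids[2:])
    base = dict(in_group=in_group, filter_group=rest, variant_table="snp")
    # raising the filter-group ceiling never shrinks the result
    prev = None
    for t in range(0, len(rest) + 1):
        res = group_filter(
            store, FilterSpec(min_in_fraction=0.5, max_filter_count=t, **base)
        ).keys()
        if prev is not None:
            assert prev <= res
        prev = res
    # raising the in-group floor never grows it
    prev = None
    for x in [0.0, 0.25, 0.5, 0.75, 1.0]:
        res = group_filter(
            store,
            FilterSpec(min_in_fraction=x, max_filter_count=len(rest), **base),
        ).keys()
        if prev is not None:
            assert res <= prev
        prev = res
    store.close()


# ---------------------------------------------------------------------------
# naive baseline
# ---------------------------------------------------------------------------

def test_naive_filter_equals_group_filter():
    rng = random.Random(7)
    for _ in range(10):
        truth, annotations = random_truth_and_annotations(rng, max_samples=6)
        ids = sorted(truth)
        if len(ids) < 3:
            continue
        store = build_store_from_truth(truth, annotations)
        spec = FilterSpec(
            in_group=frozenset(ids[:2]),
            filter_group=frozenset(ids[2:]),
            min_in_fraction=1.0,
            max_filter_count=0,
            variant_table="snp",
        )
        naive = naive_filter(store, spec)
        fast = group_filter(store, spec)
        assert naive.keys() == fast.keys()
        assert [h.summary.variant for h in naive] == [
            h.summary.variant for h in fast
        ]
        store.close()


def test_naive_filter_rejects_unsupported_shape():
    store, *_ = _trio_store()
    spec = FilterSpec(
        in_group=frozenset(["child"]),
        filter_group=frozenset(["mother", "father"]),
        max_filter_count=0,
    )
    with pytest.raises(UnsupportedInputError):
        naive_filter(store, spec)


def test_disjoint_in_group_pair_yields_empty():
    store = init_store(":memory:")
    add_sample_calls(store, "S1", [_call(VariantKey("chr1", 1, "A", "G"))])
    add_sample_calls(store, "S2", [_call(VariantKey("chr1", 2, "A", "G"))])
    add_sample_calls(store, "S3", [])
    spec = FilterSpec(in_group=frozenset(["S1", "S2"]),
                      filter_group=frozenset(["S3"]), max_filter_count=0)
    assert len(naive_filter(store, spec)) == 0


# ---------------------------------------------------------------------------
# instrumentation
# ---------------------------------------------------------------------------

def test_counters_empty_store():
    store = init_store(":memory:")
    add_sample_calls(store, "S1", [])
    spec = FilterSpec(in_group=frozenset(["S1"]), max_filter_count=0)
    counters = filter_cost_counters(store, spec)
    assert counters == {
        "summary_rows_scanned": 0,
        "per_sample_tables_opened": 0,
        "result_size": 0,
    }


def test_tables_opened_bounded_by_in_group():
    rng = random.Random(17)
    truth, annotations = random_truth_and_annotations(rng, max_samples=8)
    store = build_store_from_truth(truth, annotations)
    for _ in range(10):
        spec = random_spec(rng, truth.keys())
        counters = filter_cost_counters(store, spec)
        assert counters["per_sample_tables_opened"] <= len(spec.in_group)
    store.close()


# ---------------------------------------------------------------------------
# population filter
# ---------------------------------------------------------------------------

def _population_store():
    store = init_store(":memory:")
    labels = {}
    planted = VariantKey("chr1", 100, "A", "G")
    ann = DictAnnotator({
        planted: AnnotationResult("exonic", "nonsynonymous", "G1"),
    })
    for pop, n in [("A", 10), ("B", 10), ("C", 10)]:
        for i in range(n):
            sid = f"{pop}{i:02d}"
            labels[sid] = pop
            calls = []
            if pop == "A" and i < 5:  # 50% of population A
                calls.append(_call(planted))
            add_sample_calls(store, sid, calls, annotator=ann)
    return store, labels, planted


def test_population_filter_recovers_planted_variant():
    store, labels, planted = _population_store()
    counts, result = population_filter(store, labels, "A", 0.10, 0.01)
    assert result.keys() == {planted}
    assert counts == {"stopgain": 0, "nonsynonymous": 1, "splicing": 0,
                      "other": 0}
    assert sum(counts.values()) == len(result)
    for other in ("B", "C"):
        counts, result = population_filter(store, labels, other, 0.10, 0.01)
        assert len(result) == 0
    store.close()


def test_population_filter_below_threshold_and_unknown_label():
    store, labels, planted = _population_store()
    # 50% in A passes the 10% floor; a 60% floor rejects it
    counts, result = population_filter(store, labels, "A", 0.60, 0.01)
    assert len(result) == 0
    with pytest.raises(ValidationError):
        population_filter(store, labels, "Z", 0.1, 0.01)
    partial = dict(labels)
    partial.pop("A00")
    with pytest.raises(ValidationError, match="cover"):
        population_filter(store, partial, "A", 0.1, 0.01)
    store.close()
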