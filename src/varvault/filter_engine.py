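"""Group-based variant filtering over the summary tables.

The core analysis: samples are partitioned into an *in-group* (must carry
the variant), a *filter-group* (negative controls) and a *discard-group*
(ignored).  A variant passes when

    |carriers ∩ in_group|     >=  ceil(X · |in_group|)        and
    |carriers ∩ filter_group| <=  floor(Y · |filter_group|)   (or an
                                  absolute max_count)

with optional conjunctive constraints on annotation class, dbSNP
membership, and in-group zygosity.  Frequencies are carrier-based: a het
and a hom carrier each count once.

Because candidate selection runs entirely against the summary and carrier
link tables, the number of per-sample tables touched is bounded by
|in_group| (only to fetch genotype details of surviving variants) — the
cost of a filtering is independent of how many samples the warehouse
holds.  :func:`naive_filter` implements the join-and-loop baseline whose
table touches grow linearly with cohort size, used as an oracle and as the
performance foil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from varvault.annotate import (
    EXONIC,
    NONSYNONYMOUS,
    SPLICING,
    STOPGAIN,
    STOPLOSS,
    FRAMESHIFT,
    NO_EFFECT,
)
from varvault.datastore import (
    SummaryRecord,
    VariantStore,
    _SUMMARY_COLS,
    _summary_from_row,
)
from varvault.errors import UnsupportedInputError, ValidationError
from varvault.io_formats import GenotypeCall, VariantKey

_EPS = 1e-9

#: the "damaging" classes used when screening for candidate causative
#: mutations: nonsynonymous / stop-gain / stop-loss / frameshift coding
#: variants plus splice-site variants.
DAMAGING_CLASSES = frozenset(
    [
        (EXONIC, NONSYNONYMOUS),
        (EXONIC, STOPGAIN),
        (EXONIC, STOPLOSS),
        (EXONIC, FRAMESHIFT),
        (SPLICING, NO_EFFECT),
    ]
)


def min_carriers_required(fraction: float, group_size: int) -> int:
    """'at least X%' of n samples → ceil(X·n), float-safe."""
    return math.ceil(fraction * group_size - _EPS)


def max_carriers_allowed(fraction: float, group_size: int) -> int:
    """'at most Y%' of m samples → floor(Y·m), float-safe."""
    return math.floor(fraction * group_size + _EPS)


@dataclass(frozen=True)
class FilterSpec:
    """The in/discard/filter grouping plus thresholds and constraints.

    Exactly one of ``max_filter_fraction`` / ``max_filter_count`` must be
    set.  The three groups must be pairwise disjoint and together cover
    every registered sample; the in-group must be non-empty.
    """

    in_group: frozenset
    discard_group: frozenset = frozenset()
    filter_group: frozenset = frozenset()
    min_in_fraction: float = 1.0
    max_filter_fraction: Optional[float] = None
    max_filter_count: Optional[int] = None
    variant_table: str = "snp"
    class_constraint: Optional[frozenset] = None  # of (region, effect) pairs
    exclude_dbsnp: str = "off"  # off | all | common_only
    zygosity_constraint: str = "any"  # any | hom_in_group

    def __post_init__(self):
        object.__setattr__(self, "in_group", frozenset(self.in_group))
        object.__setattr__(self, "discard_group", frozenset(self.discard_group))
        object.__setattr__(self, "filter_group", frozenset(self.filter_group))
        if self.class_constraint is not None:
            object.__setattr__(
                self, "class_constraint", frozenset(self.class_constraint)
            )

    def validate(self, registered: Iterable[str]) -> None:
        registered = set(registered)
        if not self.in_group:
            raise ValidationError("in_group must be non-empty")
        groups = (self.in_group, self.discard_group, self.filter_group)
        if (
            self.in_group & self.discard_group
            or self.in_group & self.filter_group
            or self.discard_group & self.filter_group
        ):
            raise ValidationError("groups must be pairwise disjoint")
        union = self.in_group | self.discard_group | self.filter_group
        if union != registered:
            extra = union - registered
            missing = registered - union
            raise ValidationError(
                f"groups must partition the registered samples exactly "
                f"(unknown: {sorted(extra)}, unassigned: {sorted(missing)})"
            )
        if not (0.0 <= self.min_in_fraction <= 1.0):
            raise ValidationError("min_in_fraction must be in [0, 1]")
        if (self.max_filter_fraction is None) == (self.max_filter_count is None):
            raise ValidationError(
                "exactly one of max_filter_fraction / max_filter_count "
                "must be set"
            )
        if self.max_filter_fraction is not None and not (
            0.0 <= self.max_filter_fraction <= 1.0
        ):
            raise ValidationError("max_filter_fraction must be in [0, 1]")
        if self.max_filter_count is not None and self.max_filter_count < 0:
            raise ValidationError("max_filter_count must be >= 0")
        if self.variant_table not in ("snp", "indel"):
            raise ValidationError("variant_table must be 'snp' or 'indel'")
        if self.exclude_dbsnp not in ("off", "all", "common_only"):
            raise ValidationError(
                "exclude_dbsnp must be off, all or common_only"
            )
        if self.zygosity_constraint not in ("any", "hom_in_group"):
            raise ValidationError(
                "zygosity_constraint must be 'any' or 'hom_in_group'"
            )

    @property
    def in_threshold(self) -> int:
        return min_carriers_required(self.min_in_fraction, len(self.in_group))

    @property
    def filter_threshold(self) -> int:
        if self.max_filter_count is not None:
            return self.max_filter_count
        return max_carriers_allowed(
            self.max_filter_fraction, len(self.filter_group)
        )


@dataclass(frozen=True)
class FilterHit:
    summary: SummaryRecord
    in_carrier_count: int
    filter_carrier_count: int
    genotypes: Mapping[str, GenotypeCall]  # per surviving in-group carrier


@dataclass(frozen=True)
class FilterResult:
    """Ordered candidate list; ordering is (chrom natural, pos, alt)."""

    hits: Tuple[FilterHit, ...]
    spec: FilterSpec

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def keys(self) -> Set[VariantKey]:
        return {h.summary.variant for h in self.hits}


def _passes_annotation(rec: SummaryRecord, spec: FilterSpec) -> bool:
    if spec.class_constraint is not None:
        if (rec.region_class, rec.effect_class) not in spec.class_constraint:
            return False
    if spec.exclude_dbsnp == "all" and rec.rsid:
        return False
    if spec.exclude_dbsnp == "common_only" and rec.is_dbsnp_common:
        return False
    return True


def _fetch_genotypes(
    store: VariantStore,
    spec: FilterSpec,
    survivors: List[SummaryRecord],
    counters: dict,
) -> Dict[VariantKey, Dict[str, GenotypeCall]]:
    """Per-in-sample genotype details, fetched only for surviving variants.

    Opens at most |in_group| per-sample tables, and none when there are no
    survivors."""
    details: Dict[VariantKey, Dict[str, GenotypeCall]] = {
        rec.variant: {} for rec in survivors
    }
    if not survivors:
        return details
    wanted_samples = {
        sid
        for rec in survivors
        for sid, _zyg in rec.carriers
        if sid in spec.in_group
    }
    for sid in sorted(wanted_samples):
        table = store.calls_table(sid, spec.variant_table)
        counters["per_sample_tables_opened"] += 1
        for rec in survivors:
            v = rec.variant
            row = store.conn.execute(
                f"SELECT zygosity, ref_depth, alt_depth, quality FROM {table} "
                "WHERE chrom = ? AND pos = ? AND alt = ?",
                (v.chrom, v.pos, v.alt),
            ).fetchone()
            if row is not None:
                details[v][sid] = GenotypeCall(v, row[0], row[1], row[2], row[3])
    return details


def group_filter(store: VariantStore, spec: FilterSpec) -> FilterResult:
    """Run the group filter against the summary tables.

    Candidate selection touches only the summary and carrier link tables;
    per-sample tables are opened (at most |in_group| of them) solely to
    attach genotype details to the surviving variants.
    """
    spec.validate(store.sample_ids())
    counters = {"summary_rows_scanned": 0, "per_sample_tables_opened": 0}
    conn = store.conn
    kind = spec.variant_table
    need_in = spec.in_threshold
    max_filter = spec.filter_threshold

    where = ""
    params: list = []
    if spec.class_constraint is not None:
        if spec.class_constraint:
            clauses = " OR ".join(
                ["(region_class = ? AND effect_class = ?)"]
                * len(spec.class_constraint)
            )
            where = f" WHERE {clauses}"
            for region, effect in sorted(spec.class_constraint):
                params.extend([region, effect])
        else:
            where = " WHERE 0"

    survivors: List[Tuple[SummaryRecord, int, int]] = []
    for row in conn.execute(
        f"SELECT {_SUMMARY_COLS} FROM summary_{kind}{where}", params
    ):
        counters["summary_rows_scanned"] += 1
        rec = _summary_from_row(conn, kind, row)
        if not _passes_annotation(rec, spec):
            continue
        in_carriers = [
            (sid, zyg) for sid, zyg in rec.carriers if sid in spec.in_group
        ]
        if len(in_carriers) < need_in:
            continue
        if spec.zygosity_constraint == "hom_in_group" and any(
            zyg != "hom" for _sid, zyg in in_carriers
        ):
            continue
        f_count = sum(1 for sid, _z in rec.carriers if sid in spec.filter_group)
        if f_count > max_filter:
            continue
        survivors.append((rec, len(in_carriers), f_count))

    survivors.sort(key=lambda t: t[0].variant.sort_key())
    details = _fetch_genotypes(
        store, spec, [rec for rec, _i, _f in survivors], counters
    )
    hits = tuple(
        FilterHit(rec, i, f, details[rec.variant]) for rec, i, f in survivors
    )
    store.last_counters = counters
    return FilterResult(hits=hits, spec=spec)


def naive_filter(store: VariantStore, spec: FilterSpec) -> FilterResult:
    """The join-and-loop baseline: intersect the two in-group per-sample
    tables, then walk every filter-group sample's table to subtract.

    Restricted to the baseline shape (|in_group| = 2, X = 1.0,
    max_count = 0).  Table touches grow linearly with the filter-group
    size; the result equals :func:`group_filter` on the same spec.
    """
    spec.validate(store.sample_ids())
    if (
        len(spec.in_group) != 2
        or spec.min_in_fraction != 1.0
        or spec.max_filter_count != 0
    ):
        raise UnsupportedInputError(
            "naive_filter only supports |in_group|=2, min_in_fraction=1.0, "
            "max_filter_count=0"
        )
    counters = {"summary_rows_scanned": 0, "per_sample_tables_opened": 0}
    kind = spec.variant_table
    s1, s2 = sorted(spec.in_group)
    calls: Dict[str, Dict[VariantKey, GenotypeCall]] = {}
    for sid in (s1, s2):
        counters["per_sample_tables_opened"] += 1
        calls[sid] = {c.variant: c for c in store.read_sample_calls(sid, kind)}
    shared = set(calls[s1]) & set(calls[s2])
    for sid in sorted(spec.filter_group):
        counters["per_sample_tables_opened"] += 1
        if not shared:
            continue
        other = {c.variant for c in store.read_sample_calls(sid, kind)}
        shared -= other
    from varvault.datastore import get_summary  # local to avoid cycle at import

    survivors = []
    for v in shared:
        rec = get_summary(store, v)
        assert rec is not None, f"summary row missing for {v}"
        if not _passes_annotation(rec, spec):
            continue
        if spec.zygosity_constraint == "hom_in_group" and any(
            calls[sid][v].zygosity != "hom" for sid in (s1, s2)
        ):
            continue
        survivors.append(rec)
    survivors.sort(key=lambda r: r.variant.sort_key())
    hits = tuple(
        FilterHit(
            rec,
            2,
            0,
            {sid: calls[sid][rec.variant] for sid in (s1, s2)},
        )
        for rec in survivors
    )
    store.last_counters = counters
    return FilterResult(hits=hits, spec=spec)


def population_filter(
    store: VariantStore,
    population_labels: Mapping[str, str],
    target_label: str,
    min_target_fraction: float,
    max_other_fraction: float,
    class_breakdown: bool = True,
    variant_table: str = "snp",
) -> Tuple[Dict[str, int], FilterResult]:
    """Population-specific variants: present in at least
    ``min_target_fraction`` of the target population and at most
    ``max_other_fraction`` of everyone else.

    Returns (per-class counts, FilterResult); counts are partitioned into
    stopgain / nonsynonymous / splicing / other and sum to the result size.
    """
    registered = store.sample_ids()
    missing = [s for s in registered if s not in population_labels]
    if missing:
        raise ValidationError(
            f"population_labels must cover all samples; missing {missing}"
        )
    target = frozenset(
        s for s in registered if population_labels[s] == target_label
    )
    if not target:
        raise ValidationError(f"unknown population label {target_label!r}")
    others = frozenset(registered) - target
    spec = FilterSpec(
        in_group=target,
        filter_group=others,
        min_in_fraction=min_target_fraction,
        max_filter_fraction=max_other_fraction,
        variant_table=variant_table,
    )
    result = group_filter(store, spec)
    counts = {"stopgain": 0, "nonsynonymous": 0, "splicing": 0, "other": 0}
    if class_breakdown:
        for hit in result:
            rec = hit.summary
            if rec.effect_class == STOPGAIN:
                counts["stopgain"] += 1
            elif rec.effect_class == NONSYNONYMOUS:
                counts["nonsynonymous"] += 1
            elif rec.region_class == SPLICING:
                counts["splicing"] += 1
            else:
                counts["other"] += 1
    return counts, result


def filter_cost_counters(store: VariantStore, spec: FilterSpec) -> dict:
    """Run :func:`group_filter` with instrumentation and return the counters
    (summary rows scanned, per-sample tables opened, result size)."""
    result = group_filter(store, spec)
    counters = dict(store.last_counters)
    counters["result_size"] = len(result)
    return counters


# ---------------------------------------------------------------------------
# result rendering
# ---------------------------------------------------------------------------

_DISPLAY_REGION = {
    "intronic": "Intronic",
    "intergenic": "Intergenic",
    "splicing": "Splicing",
    "UTR5": "UTR5",
    "UTR3": "UTR3",
    "upstream": "Upstream",
    "downstream": "Downstream",
    "ncRNA": "ncRNA",
}

_DISPLAY_EFFECT = {
    "nonsynonymous": "Nonsynonymous",
    "synonymous": "Synonymous",
    "stopgain": "Stopgain",
    "stoploss": "Stoploss",
    "frameshift": "Frameshift",
    "nonframeshift": "Nonframeshift",
    "none": "Exonic",
}


def display_class(rec: SummaryRecord) -> str:
    """Human-readable class column: the coding effect for exonic variants,
    the region otherwise."""
    if rec.region_class == EXONIC:
        return _DISPLAY_EFFECT[rec.effect_class]
    return _DISPLAY_REGION.get(rec.region_class, rec.region_class)


def result_to_tsv(result: FilterResult) -> str:
    """Render a FilterResult as a diffable TSV (Pos, Rsid, Class, Gene,
    alleles, carrier counts, per-in-sample genotypes)."""
    in_samples = sorted(result.spec.in_group)
    header = (
        ["Pos", "Rsid", "Class", "Gene", "Ref", "Alt", "InCarriers",
         "FilterCarriers"]
        + [f"GT:{sid}" for sid in in_samples]
    )
    lines = ["\t".join(header)]
    for hit in result:
        rec = hit.summary
        v = rec.variant
        row = [
            f"{v.chrom}:{v.pos}",
            rec.rsid,
            display_class(rec),
            rec.gene_symbol,
            v.ref,
            v.alt,
            str(hit.in_carrier_count),
            str(hit.filter_carrier_count),
        ]
        for sid in in_samples:
            call = hit.genotypes.get(sid)
            row.append(
                ""
                if call is None
                else f"{call.zygosity}({call.ref_depth}/{call.alt_depth},"
                     f"q{format(call.quality, 'g')})"
            )
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def write_filter_result(result: FilterResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(result_to_tsv(result))
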