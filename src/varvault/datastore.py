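"""The variant warehouse: per-sample call tables plus denormalized summary tables.

Layout (one SQLite database):

* ``samples`` — the sample registry (id, description, platform, counts);
* one physical call table per sample and variant kind
  (``calls_snp_<idx>`` / ``calls_indel_<idx>``), holding that sample's raw
  genotype calls;
* ``summary_snp`` / ``summary_indel`` — one row per distinct variant with
  its annotation, indexed by (chrom, pos, alt) and by
  (region_class, effect_class);
* ``carriers_snp`` / ``carriers_indel`` — the carrier link tables
  (variant_id, sample_id, zygosity), indexed by variant_id, with a cached
  ``n_carriers`` on the summary row.

Every mutation path (add sample, batch import, remove sample) runs in one
transaction and keeps the summary tables consistent with the per-sample
tables; :func:`audit_check` verifies that consistency by full scan and
:func:`audit_dump` renders the canonical, deterministic equality surface
used by the tests.

Annotation is performed exactly once per distinct variant over the store's
lifetime: a variant already present in a summary table only has its carrier
set extended.
"""

from __future__ import annotations

import datetime
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from varvault.annotate import Annotator, INTERGENIC_RESULT
from varvault.errors import StoreError, ValidationError, VarVaultError
from varvault.io_formats import (
    GenotypeCall,
    SampleSheetRow,
    VariantKey,
    chrom_sort_key,
    read_internal_variants,
    read_vcf_variants,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
KINDS = ("snp", "indel")

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE samples (
    sample_idx  INTEGER PRIMARY KEY AUTOINCREMENT,
    sample_id   TEXT UNIQUE NOT NULL,
    description TEXT NOT NULL DEFAULT '',
    platform    TEXT NOT NULL DEFAULT '',
    import_time TEXT NOT NULL,
    n_snps      INTEGER NOT NULL DEFAULT 0,
    n_indels    INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE summary_snp (
    variant_id      INTEGER PRIMARY KEY AUTOINCREMENT,
    chrom           TEXT NOT NULL,
    pos             INTEGER NOT NULL,
    ref             TEXT NOT NULL,
    alt             TEXT NOT NULL,
    n_carriers      INTEGER NOT NULL,
    rsid            TEXT NOT NULL DEFAULT '',
    is_dbsnp_common INTEGER NOT NULL DEFAULT 0,
    region_class    TEXT NOT NULL,
    effect_class    TEXT NOT NULL,
    gene_symbol     TEXT NOT NULL DEFAULT '',
    scores          TEXT NOT NULL DEFAULT '{}'
);
CREATE UNIQUE INDEX idx_summary_snp_key ON summary_snp (chrom, pos, alt);
CREATE INDEX idx_summary_snp_class ON summary_snp (region_class, effect_class);
CREATE TABLE carriers_snp (
    variant_id INTEGER NOT NULL,
    sample_id  TEXT NOT NULL,
    zygosity   TEXT NOT NULL,
    PRIMARY KEY (variant_id, sample_id)
);
CREATE INDEX idx_carriers_snp_sample ON carriers_snp (sample_id);
CREATE TABLE summary_indel (
    variant_id      INTEGER PRIMARY KEY AUTOINCREMENT,
    chrom           TEXT NOT NULL,
    pos             INTEGER NOT NULL,
    ref             TEXT NOT NULL,
    alt             TEXT NOT NULL,
    n_carriers      INTEGER NOT NULL,
    rsid            TEXT NOT NULL DEFAULT '',
    is_dbsnp_common INTEGER NOT NULL DEFAULT 0,
    region_class    TEXT NOT NULL,
    effect_class    TEXT NOT NULL,
    gene_symbol     TEXT NOT NULL DEFAULT '',
    scores          TEXT NOT NULL DEFAULT '{}'
);
CREATE UNIQUE INDEX idx_summary_indel_key ON summary_indel (chrom, pos, alt);
CREATE INDEX idx_summary_indel_class ON summary_indel (region_class, effect_class);
CREATE TABLE carriers_indel (
    variant_id INTEGER NOT NULL,
    sample_id  TEXT NOT NULL,
    zygosity   TEXT NOT NULL,
    PRIMARY KEY (variant_id, sample_id)
);
CREATE INDEX idx_carriers_indel_sample ON carriers_indel (sample_id);
"""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    description: str
    platform: str
    import_time: str
    n_snps: int
    n_indels: int


@dataclass(frozen=True)
class SummaryRecord:
    """The denormalized row powering fast filtering."""

    variant: VariantKey
    carriers: frozenset  # of (sample_id, zygosity)
    n_carriers: int
    rsid: str
    is_dbsnp_common: bool
    region_class: str
    effect_class: str
    gene_symbol: str
    scores: dict


@dataclass
class ImportReport:
    imported: List[str] = field(default_factory=list)
    skipped: List[str] = field(default_factory=list)
    failed: Dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "imported": len(self.imported),
            "skipped": len(self.skipped),
            "failed": len(self.failed),
        }


@dataclass(frozen=True)
class RemovalReport:
    sample_id: str
    snps_decremented: int
    snps_deleted: int
    indels_decremented: int
    indels_deleted: int


class VariantStore:
    """Opaque handle to an initialized warehouse (StoreHandle)."""

    def __init__(self, conn: sqlite3.Connection, path: str):
        self.conn = conn
        self.path = path
        self.last_counters: Optional[dict] = None  # set by the filter engine

    # -- registry helpers ---------------------------------------------------

    def sample_ids(self) -> List[str]:
        rows = self.conn.execute(
            "SELECT sample_id FROM samples ORDER BY sample_id"
        ).fetchall()
        return [r[0] for r in rows]

    def has_sample(self, sample_id: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM samples WHERE sample_id = ?", (sample_id,)
        ).fetchone()
        return row is not None

    def _sample_idx(self, sample_id: str) -> int:
        row = self.conn.execute(
            "SELECT sample_idx FROM samples WHERE sample_id = ?", (sample_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown sample: {sample_id!r}")
        return row[0]

    def calls_table(self, sample_id: str, kind: str) -> str:
        """Physical per-sample call-table name for a registered sample."""
        return f"calls_{kind}_{self._sample_idx(sample_id)}"

    def read_sample_calls(self, sample_id: str, kind: str) -> List[GenotypeCall]:
        table = self.calls_table(sample_id, kind)
        rows = self.conn.execute(
            f"SELECT chrom, pos, ref, alt, zygosity, ref_depth, alt_depth, "
            f"quality FROM {table}"
        ).fetchall()
        return [
            GenotypeCall(
                VariantKey(r[0], r[1], r[2], r[3]), r[4], r[5], r[6], r[7]
            )
            for r in rows
        ]

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "VariantStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def _connect(path: str) -> sqlite3.Connection:
    conn = sqlite3.connect(path)
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def init_store(path, overwrite: bool = False) -> VariantStore:
    """Create an empty warehouse at ``path`` (":memory:" for an in-memory
    store).  Refuses to clobber an existing store unless ``overwrite``."""
    path = str(path)
    if path != ":memory:":
        p = Path(path)
        if p.exists():
            if not overwrite:
                raise StoreError(
                    f"store already exists at {path}; pass overwrite=True "
                    "to replace it"
                )
            p.unlink()
        p.parent.mkdir(parents=True, exist_ok=True)
    conn = _connect(path)
    conn.executescript(_SCHEMA)
    conn.execute(
        "INSERT INTO meta (key, value) VALUES ('schema_version', ?)",
        (SCHEMA_VERSION,),
    )
    conn.commit()
    return VariantStore(conn, path)


def open_store(path) -> VariantStore:
    """Open an existing warehouse."""
    path = str(path)
    if path != ":memory:" and not Path(path).exists():
        raise StoreError(f"no store at {path}")
    conn = _connect(path)
    row = conn.execute(
        "SELECT value FROM meta WHERE key = 'schema_version'"
    ).fetchone()
    if row is None or row[0] != SCHEMA_VERSION:
        conn.close()
        raise StoreError(f"{path} is not a varvault store (schema mismatch)")
    return VariantStore(conn, path)


# ---------------------------------------------------------------------------
# imports
# ---------------------------------------------------------------------------

def _parse_row_calls(row: SampleSheetRow) -> Tuple[list, list]:
    if row.format == "vcf":
        if row.snp_path is None:
            raise ValidationError(
                f"sample {row.sample_id}: VCF rows must set snp_path to the VCF"
            )
        return read_vcf_variants(row.snp_path)
    snps = (
        read_internal_variants(row.snp_path, "snp") if row.snp_path else []
    )
    indels = (
        read_internal_variants(row.indel_path, "indel") if row.indel_path else []
    )
    return snps, indels


def _dedupe(calls: Iterable[GenotypeCall]) -> List[GenotypeCall]:
    seen = set()
    out = []
    for c in calls:
        if c.variant in seen:
            logger.warning("duplicate call for %s in one sample; keeping first",
                           c.variant)
            continue
        seen.add(c.variant)
        out.append(c)
    return out


def _insert_calls(
    conn: sqlite3.Connection,
    sample_id: str,
    sample_idx: int,
    kind: str,
    calls: List[GenotypeCall],
    annotator: Optional[Annotator],
) -> None:
    table = f"calls_{kind}_{sample_idx}"
    conn.execute(
        f"CREATE TABLE {table} ("
        "chrom TEXT, pos INTEGER, ref TEXT, alt TEXT, zygosity TEXT, "
        "ref_depth INTEGER, alt_depth INTEGER, quality REAL)"
    )
    conn.execute(f"CREATE INDEX idx_{table}_key ON {table} (chrom, pos, alt)")
    conn.executemany(
        f"INSERT INTO {table} VALUES (?,?,?,?,?,?,?,?)",
        [
            (
                c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt,
                c.zygosity, c.ref_depth, c.alt_depth, c.quality,
            )
            for c in calls
        ],
    )
    summary = f"summary_{kind}"
    carriers = f"carriers_{kind}"
    for c in calls:
        v = c.variant
        row = conn.execute(
            f"SELECT variant_id, ref FROM {summary} "
            "WHERE chrom = ? AND pos = ? AND alt = ?",
            (v.chrom, v.pos, v.alt),
        ).fetchone()
        if row is not None:
            variant_id, existing_ref = row
            if existing_ref != v.ref:
                raise StoreError(
                    f"{v.chrom}:{v.pos} alt {v.alt}: ref {v.ref!r} from "
                    f"sample {sample_id} conflicts with stored ref "
                    f"{existing_ref!r}"
                )
            conn.execute(
                f"UPDATE {summary} SET n_carriers = n_carriers + 1 "
                "WHERE variant_id = ?",
                (variant_id,),
            )
        else:
            ann = (
                annotator.annotate(v) if annotator is not None
                else INTERGENIC_RESULT
            )
            cur = conn.execute(
                f"INSERT INTO {summary} (chrom, pos, ref, alt, n_carriers, "
                "rsid, is_dbsnp_common, region_class, effect_class, "
                "gene_symbol, scores) VALUES (?,?,?,?,1,?,?,?,?,?,?)",
                (
                    v.chrom, v.pos, v.ref, v.alt, ann.rsid,
                    int(ann.is_dbsnp_common), ann.region_class,
                    ann.effect_class, ann.gene_symbol,
                    json.dumps(ann.scores, sort_keys=True),
                ),
            )
            variant_id = cur.lastrowid
        conn.execute(
            f"INSERT INTO {carriers} (variant_id, sample_id, zygosity) "
            "VALUES (?,?,?)",
            (variant_id, sample_id, c.zygosity),
        )


def add_sample_calls(
    store: VariantStore,
    sample_id: str,
    snps: Iterable[GenotypeCall],
    indels: Iterable[GenotypeCall] = (),
    annotator: Optional[Annotator] = None,
    description: str = "",
    platform: str = "",
) -> Optional[SampleRecord]:
    """Import one sample from already-parsed calls (see :func:`add_sample`
    for the file-driven entry point).  Atomic; duplicate sample ids are
    skipped with a logged notice and None is returned."""
    if store.has_sample(sample_id):
        logger.info("sample %r already in store; not imported", sample_id)
        return None
    snps, indels = _dedupe(snps), _dedupe(indels)
    for kind, calls in (("snp", snps), ("indel", indels)):
        for c in calls:
            if c.variant.kind != kind:
                raise ValidationError(
                    f"{c.variant} is a {c.variant.kind}; cannot import as {kind}"
                )
    conn = store.conn
    now = datetime.datetime.now(datetime.timezone.utc).isoformat()
    try:
        cur = conn.execute(
            "INSERT INTO samples (sample_id, description, platform, "
            "import_time, n_snps, n_indels) VALUES (?,?,?,?,?,?)",
            (sample_id, description, platform, now, len(snps), len(indels)),
        )
        sample_idx = cur.lastrowid
        _insert_calls(conn, sample_id, sample_idx, "snp", snps, annotator)
        _insert_calls(conn, sample_id, sample_idx, "indel", indels, annotator)
    except Exception:
        conn.rollback()
        raise
    conn.commit()
    return SampleRecord(
        sample_id, description, platform, now, len(snps), len(indels)
    )


def add_sample(
    store: VariantStore,
    row: SampleSheetRow,
    annotator: Optional[Annotator] = None,
) -> Optional[SampleRecord]:
    """Import one sample: parse its files, write its call tables, and fold
    its variants into the summary tables.

    A sample_id already in the registry is skipped with a logged notice
    (batch semantics) and None is returned.  The import is atomic: on any
    failure the store is unchanged.
    """
    if store.has_sample(row.sample_id):
        logger.info("sample %r already in store; not imported", row.sample_id)
        return None
    snps, indels = _parse_row_calls(row)
    return add_sample_calls(
        store,
        row.sample_id,
        snps,
        indels,
        annotator=annotator,
        description=row.description,
        platform=row.platform,
    )


def batch_import(
    store: VariantStore,
    sheet: Iterable[SampleSheetRow],
    annotator: Optional[Annotator] = None,
) -> ImportReport:
    """Import a validated sample sheet in order.

    Existing samples are skipped; a failing sample aborts only itself and
    is recorded in the report.
    """
    report = ImportReport()
    for row in sheet:
        if store.has_sample(row.sample_id):
            logger.info("sample %r already in store; skipped", row.sample_id)
            report.skipped.append(row.sample_id)
            continue
        try:
            rec = add_sample(store, row, annotator)
        except VarVaultError as exc:
            logger.error("import of %r failed: %s", row.sample_id, exc)
            report.failed[row.sample_id] = str(exc)
            continue
        assert rec is not None
        report.imported.append(row.sample_id)
    return report


def remove_sample(store: VariantStore, sample_id: str) -> RemovalReport:
    """Remove a sample: drop its call tables, shrink carrier sets, delete
    summary rows whose carrier set becomes empty."""
    conn = store.conn
    sample_idx = store._sample_idx(sample_id)  # raises StoreError if unknown
    stats = {}
    try:
        for kind in KINDS:
            summary = f"summary_{kind}"
            carriers = f"carriers_{kind}"
            ids = [
                r[0]
                for r in conn.execute(
                    f"SELECT variant_id FROM {carriers} WHERE sample_id = ?",
                    (sample_id,),
                )
            ]
            conn.execute(
                f"DELETE FROM {carriers} WHERE sample_id = ?", (sample_id,)
            )
            deleted = 0
            for vid in ids:
                cur = conn.execute(
                    f"UPDATE {summary} SET n_carriers = n_carriers - 1 "
                    "WHERE variant_id = ?",
                    (vid,),
                )
            cur = conn.execute(
                f"DELETE FROM {summary} WHERE n_carriers <= 0"
            )
            deleted = cur.rowcount
            stats[kind] = (len(ids) - deleted, deleted)
            conn.execute(f"DROP TABLE IF EXISTS calls_{kind}_{sample_idx}")
        conn.execute("DELETE FROM samples WHERE sample_id = ?", (sample_id,))
    except Exception:
        conn.rollback()
        raise
    conn.commit()
    return RemovalReport(
        sample_id=sample_id,
        snps_decremented=stats["snp"][0],
        snps_deleted=stats["snp"][1],
        indels_decremented=stats["indel"][0],
        indels_deleted=stats["indel"][1],
    )


# ---------------------------------------------------------------------------
# lookups and statistics
# ---------------------------------------------------------------------------

def _summary_from_row(conn, kind: str, row) -> SummaryRecord:
    (variant_id, chrom, pos, ref, alt, n_carriers, rsid, common, region,
     effect, gene, scores) = row
    carriers = frozenset(
        (r[0], r[1])
        for r in conn.execute(
            f"SELECT sample_id, zygosity FROM carriers_{kind} "
            "WHERE variant_id = ?",
            (variant_id,),
        )
    )
    return SummaryRecord(
        variant=VariantKey(chrom, pos, ref, alt),
        carriers=carriers,
        n_carriers=n_carriers,
        rsid=rsid,
        is_dbsnp_common=bool(common),
        region_class=region,
        effect_class=effect,
        gene_symbol=gene,
        scores=json.loads(scores),
    )


_SUMMARY_COLS = (
    "variant_id, chrom, pos, ref, alt, n_carriers, rsid, is_dbsnp_common, "
    "region_class, effect_class, gene_symbol, scores"
)


def get_summary(
    store: VariantStore, variant: VariantKey
) -> Optional[SummaryRecord]:
    """Exact-key lookup against the summary index; None when absent."""
    kind = variant.kind
    row = store.conn.execute(
        f"SELECT {_SUMMARY_COLS} FROM summary_{kind} "
        "WHERE chrom = ? AND pos = ? AND alt = ?",
        (variant.chrom, variant.pos, variant.alt),
    ).fetchone()
    if row is None or row[3] != variant.ref:
        return None
    return _summary_from_row(store.conn, kind, row)


def store_stats(store: VariantStore) -> dict:
    """Per-sample and global counts, suitable for a per-sample variant-count
    table."""
    conn = store.conn
    samples = [
        SampleRecord(*r)
        for r in conn.execute(
            "SELECT sample_id, description, platform, import_time, n_snps, "
            "n_indels FROM samples ORDER BY sample_id"
        )
    ]
    out = {
        "n_samples": len(samples),
        "samples": samples,
        "total_snp_calls": sum(s.n_snps for s in samples),
        "total_indel_calls": sum(s.n_indels for s in samples),
    }
    for kind in KINDS:
        row = conn.execute(f"SELECT COUNT(*) FROM summary_{kind}").fetchone()
        out[f"distinct_{kind}s"] = row[0]
        tallies = {}
        for region, effect, n in conn.execute(
            f"SELECT region_class, effect_class, COUNT(*) FROM summary_{kind} "
            "GROUP BY region_class, effect_class"
        ):
            tallies[(region, effect)] = n
        out[f"{kind}_class_tallies"] = tallies
    return out


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def audit_dump(store: VariantStore) -> str:
    """Deterministic TSV of the whole warehouse: the canonical equality
    surface.  Sorted by (table, chrom natural order, pos, alt); carriers
    rendered as 'sample:zygosity' sorted by sample id."""
    conn = store.conn
    lines = ["table\tchrom\tpos\tref\talt\tcarriers\tregion\teffect\tgene\trsid"]
    for kind in KINDS:
        rows = conn.execute(
            f"SELECT {_SUMMARY_COLS} FROM summary_{kind}"
        ).fetchall()
        recs = [_summary_from_row(conn, kind, r) for r in rows]
        recs.sort(key=lambda r: r.variant.sort_key())
        for rec in recs:
            carriers = ";".join(
                f"{sid}:{zyg}" for sid, zyg in sorted(rec.carriers)
            )
            v = rec.variant
            lines.append(
                f"{kind}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{carriers}\t"
                f"{rec.region_class}\t{rec.effect_class}\t{rec.gene_symbol}\t"
                f"{rec.rsid}"
            )
    return "\n".join(lines) + "\n"


def audit_check(store: VariantStore) -> List[str]:
    """Full-scan consistency audit; returns a list of problems (empty =
    consistent).

    Checks, per variant kind: (1) the carrier link table equals the
    ground-truth carrier sets recomputed from every per-sample call table;
    (2) cached n_carriers equals the true carrier count and is >= 1;
    (3) registry n_snps/n_indels equal the call-table row counts;
    (4) conservation: total calls across samples equal the sum of
    n_carriers across summary rows.
    """
    conn = store.conn
    problems: List[str] = []
    sample_ids = store.sample_ids()
    for kind in KINDS:
        truth: Dict[tuple, dict] = {}
        total_calls = 0
        for sid in sample_ids:
            idx = store._sample_idx(sid)
            rows = conn.execute(
                f"SELECT chrom, pos, ref, alt, zygosity "
                f"FROM calls_{kind}_{idx}"
            ).fetchall()
            n_col = "n_snps" if kind == "snp" else "n_indels"
            reg = conn.execute(
                f"SELECT {n_col} FROM samples WHERE sample_id = ?", (sid,)
            ).fetchone()[0]
            if reg != len(rows):
                problems.append(
                    f"{sid}: registry {n_col}={reg} but call table has "
                    f"{len(rows)} rows"
                )
            total_calls += len(rows)
            for chrom, pos, ref, alt, zyg in rows:
                truth.setdefault((chrom, pos, ref, alt), {})[sid] = zyg
        summary_rows = conn.execute(
            f"SELECT {_SUMMARY_COLS} FROM summary_{kind}"
        ).fetchall()
        seen_keys = set()
        n_carrier_sum = 0
        for row in summary_rows:
            rec = _summary_from_row(conn, kind, row)
            key = (rec.variant.chrom, rec.variant.pos, rec.variant.ref,
                   rec.variant.alt)
            seen_keys.add(key)
            n_carrier_sum += rec.n_carriers
            expected = truth.get(key, {})
            actual = {sid: zyg for sid, zyg in rec.carriers}
            if actual != expected:
                problems.append(
                    f"{kind} {rec.variant}: carriers {actual} != per-sample "
                    f"truth {expected}"
                )
            if rec.n_carriers != len(rec.carriers) or rec.n_carriers < 1:
                problems.append(
                    f"{kind} {rec.variant}: cached n_carriers "
                    f"{rec.n_carriers} != {len(rec.carriers)}"
                )
        missing = set(truth) - seen_keys
        for key in sorted(missing):
            problems.append(f"{kind} {key}: in per-sample tables but not in summary")
        if n_carrier_sum != total_calls:
            problems.append(
                f"{kind}: conservation violated: sum n_carriers "
                f"{n_carrier_sum} != total calls {total_calls}"
            )
    return problems
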