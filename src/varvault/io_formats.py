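"""Readers and writers for every external file format, plus the core domain types.

All inputs — the internal tab-separated variant format, single-sample VCF,
sample sheets, and genePred/refFlat gene models — are normalized at this
boundary into one internal representation:

* coordinates are 1-based inclusive everywhere inside the package
  (genePred's 0-based half-open convention is converted on read/write);
* indels use the "-" allele notation: a pure insertion has ``ref == "-"``,
  a pure deletion has ``alt == "-"``; VCF's anchored-base representation is
  reduced to this form by stripping the maximal common prefix and suffix of
  REF/ALT and left-aligning against the REF allele string (no reference
  genome is consulted);
* chromosome names are stored verbatim; mixing "chr1" and "1" in one
  dataset logs a warning but is not an error.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from varvault.errors import (
    FormatError,
    InputError,
    ParseError,
    UnsupportedInputError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
HET = "het"
HOM = "hom"
ZYGOSITIES = (HET, HOM)

INTERNAL_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "zygosity",
    "ref_depth",
    "alt_depth",
    "quality",
)

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "description",
    "platform",
    "format",
    "snp_path",
    "indel_path",
)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural-sort key for chromosome names: chr2 < chr10 < chrX."""
    parts: list = []
    num = ""
    for ch in chrom:
        if ch.isdigit():
            num += ch
        else:
            if num:
                parts.append((0, int(num)))
                num = ""
            parts.append((1, ch))
    if num:
        parts.append((0, int(num)))
    return tuple(parts)


def _check_allele(value: str, name: str) -> None:
    if not value:
        raise ValidationError(f"{name} allele must be non-empty")
    if value == "-":
        return
    if not set(value) <= _BASES:
        raise ValidationError(
            f"{name} allele {value!r} must be over A,C,G,T or be '-'"
        )


@dataclass(frozen=True, order=False)
class VariantKey:
    """Canonical identity of a variant: chromosome, 1-based position, ref, alt.

    ``ref == "-"`` denotes a pure insertion, ``alt == "-"`` a pure deletion.
    A key is a SNP iff both alleles are single bases.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        _check_allele(self.ref, "ref")
        _check_allele(self.alt, "alt")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt must differ, both are {self.ref!r}"
            )
        if self.ref == "-" and self.alt == "-":
            raise ValidationError("ref and alt cannot both be '-'")

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref != "-"
            and self.alt != "-"
        )

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def kind(self) -> str:
        return "snp" if self.is_snp else "indel"

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.alt, self.ref)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's observation of a variant."""

    variant: VariantKey
    zygosity: str
    ref_depth: int
    alt_depth: int
    quality: float

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValidationError(
                f"zygosity must be one of {ZYGOSITIES}, got {self.zygosity!r}"
            )
        if self.ref_depth < 0:
            raise ValidationError("ref_depth must be non-negative")
        if self.alt_depth < 1:
            raise ValidationError(
                "alt_depth must be >= 1 (a call implies a supporting read)"
            )
        if self.quality < 0:
            raise ValidationError("quality must be non-negative")


@dataclass(frozen=True)
class SampleSheetRow:
    """One row of a batch-import sample sheet."""

    sample_id: str
    description: str
    platform: str
    format: str  # "internal" or "vcf"
    snp_path: Optional[Path]
    indel_path: Optional[Path]

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.format not in ("internal", "vcf"):
            raise ValidationError(
                f"format must be 'internal' or 'vcf', got {self.format!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure in 1-based inclusive coordinates.

    ``cds_start``/``cds_end`` are None for noncoding models.  ``cds_seq``,
    when present, is the spliced coding sequence in coding orientation
    (already reverse-complemented for minus-strand models); its length must
    equal the exonic base count within the CDS span and be a multiple of 3.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: Optional[int]
    cds_end: Optional[int]
    exon_starts: tuple
    exon_ends: tuple
    cds_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValidationError(
                f"{self.transcript_id}: exon start/end lists differ in length"
            )
        if not self.exon_starts:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s > e:
                raise ValidationError(f"{self.transcript_id}: exon {s}-{e} inverted")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if self.exon_starts[0] < self.tx_start or self.exon_ends[-1] > self.tx_end:
            raise ValidationError(
                f"{self.transcript_id}: exons outside transcript span"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(
                f"{self.transcript_id}: cds_start/cds_end must both be set or unset"
            )
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
                raise ValidationError(
                    f"{self.transcript_id}: CDS span outside transcript span"
                )
        if self.cds_seq is not None:
            if self.cds_start is None:
                raise ValidationError(
                    f"{self.transcript_id}: cds_seq given for noncoding model"
                )
            clen = self.coding_length
            if len(self.cds_seq) != clen:
                raise ValidationError(
                    f"{self.transcript_id}: cds_seq length {len(self.cds_seq)} "
                    f"!= exonic CDS length {clen}"
                )
            if clen % 3 != 0:
                raise ValidationError(
                    f"{self.transcript_id}: CDS length {clen} not a multiple of 3"
                )
            if not set(self.cds_seq) <= _BASES:
                raise ValidationError(f"{self.transcript_id}: cds_seq has non-ACGT")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def exons(self) -> list:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def coding_length(self) -> int:
        if not self.is_coding:
            return 0
        total = 0
        for s, e in zip(self.exon_starts, self.exon_ends):
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                total += hi - lo + 1
        return total


# ---------------------------------------------------------------------------
# internal variant format
# ---------------------------------------------------------------------------

def _classify_kind_ok(key: VariantKey, kind: str) -> bool:
    return (kind == "snp") == key.is_snp


def read_internal_variants(path, kind: str) -> list:
    """Read the internal tab-separated variant format.

    Columns: chrom, pos, ref, alt, zygosity, ref_depth, alt_depth, quality.
    ``kind`` ("snp" or "indel") is enforced: a SNP file containing an indel
    key (or vice versa) raises ValidationError.
    """
    if kind not in ("snp", "indel"):
        raise ValidationError(f"kind must be 'snp' or 'indel', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"variant file not found: {path}")
    calls: list = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (header row required)")
        if tuple(header) != INTERNAL_COLUMNS:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {list(INTERNAL_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(INTERNAL_COLUMNS):
                raise ParseError(
                    f"{path} line {lineno}: expected {len(INTERNAL_COLUMNS)} "
                    f"columns, got {len(row)}"
                )
            try:
                key = VariantKey(row[0], int(row[1]), row[2], row[3])
                call = GenotypeCall(
                    key, row[4], int(row[5]), int(row[6]), float(row[7])
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            if not _classify_kind_ok(key, kind):
                raise ValidationError(
                    f"{path} line {lineno}: {key} is a {key.kind}, "
                    f"but the file was declared kind={kind}"
                )
            calls.append(call)
    return calls


def _fmt_quality(q: float) -> str:
    return format(q, "g")


def write_internal_variants(path, calls: Iterable[GenotypeCall]) -> None:
    """Write calls in the internal tab-separated format (round-trips with
    :func:`read_internal_variants` up to float formatting)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INTERNAL_COLUMNS)
        for c in calls:
            v = c.variant
            writer.writerow(
                [
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    c.zygosity,
                    c.ref_depth,
                    c.alt_depth,
                    _fmt_quality(c.quality),
                ]
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def normalize_vcf_allele(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce a VCF REF/ALT pair to the internal representation.

    Strips the maximal common prefix, then the maximal common suffix, then
    left-aligns pure insertions/deletions against the REF allele string.
    The returned position is the first affected base (for pure insertions:
    the base after which the insertion occurs).
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref == alt:
        raise ValidationError(f"{chrom}:{pos}: REF equals ALT ({ref})")
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    r, a = ref[p:], alt[p:]
    s = 0
    while s < min(len(r), len(a)) and r[len(r) - 1 - s] == a[len(a) - 1 - s]:
        s += 1
    if s:
        r, a = r[:-s], a[:-s]
    if r and a:
        # substitution (SNP or block substitution)
        return VariantKey(chrom, pos + p, r, a)
    if not r:
        # pure insertion of `a` after REF offset p-1; left-rotate
        ins, k = a, p
        while k > 0 and ref[k - 1] == ins[-1]:
            ins = ref[k - 1] + ins[:-1]
            k -= 1
        return VariantKey(chrom, max(pos + k - 1, 1), "-", ins)
    # pure deletion of `r` at REF offset p; left-rotate
    dele, k = r, p
    while k > 0 and ref[k - 1] == dele[-1]:
        dele = ref[k - 1] + dele[:-1]
        k -= 1
    return VariantKey(chrom, pos + k, dele, "-")


def normalize_variant_key(key: VariantKey) -> VariantKey:
    """Normalize an internal key; idempotent.  Keys already using the '-'
    notation are returned unchanged."""
    if key.ref == "-" or key.alt == "-":
        return key
    return normalize_vcf_allele(key.chrom, key.pos, key.ref, key.alt)


def read_vcf_variants(path):
    """Read a single-sample VCF into (snps, indels) lists of GenotypeCall.

    Each ALT allele of each record becomes an independent call; GT with one
    copy of the allele maps to het, all copies to hom.  0/0 and ./. records
    are skipped; half-calls like ./1 are rejected.  AD supplies depths when
    present, else DP, else a 0/1 placeholder with a logged warning.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise InputError(f"VCF not found: {path}")
    snps: list = []
    indels: list = []
    warned_depth = False
    with pysam.VariantFile(str(path)) as vf:
        n_samples = len(vf.header.samples)
        if n_samples != 1:
            raise UnsupportedInputError(
                f"{path}: expected a single-sample VCF, found {n_samples} "
                "samples (split batch VCFs before import)"
            )
        for rec in vf:
            if "GT" not in rec.format:
                raise FormatError(
                    f"{path}: record {rec.contig}:{rec.pos} has no GT field"
                )
            sample = rec.samples[0]
            gt = sample["GT"]
            if gt is None or all(a is None for a in gt):
                continue  # ./.
            if any(a is None for a in gt):
                raise ParseError(
                    f"{path}: half-call genotype at {rec.contig}:{rec.pos}"
                )
            if all(a == 0 for a in gt):
                continue  # 0/0
            alts = rec.alts or ()
            ad = sample.get("AD")
            dp = sample.get("DP")
            for i, alt in enumerate(alts, start=1):
                if i not in gt:
                    continue
                if alt is None or not set(alt.upper()) <= _BASES:
                    logger.warning(
                        "%s: skipping symbolic/unsupported ALT %r at %s:%d",
                        path, alt, rec.contig, rec.pos,
                    )
                    continue
                zyg = HOM if all(a == i for a in gt) else HET
                if ad is not None and len(ad) > i and ad[i] is not None:
                    ref_depth = int(ad[0] or 0)
                    alt_depth = max(int(ad[i]), 1)
                elif dp is not None:
                    ref_depth = max(int(dp) - 1, 0)
                    alt_depth = 1
                else:
                    if not warned_depth:
                        logger.warning(
                            "%s: no AD/DP fields; using 0/1 depth placeholders",
                            path,
                        )
                        warned_depth = True
                    ref_depth, alt_depth = 0, 1
                key = normalize_vcf_allele(rec.contig, rec.pos, rec.ref, alt)
                call = GenotypeCall(
                    key, zyg, ref_depth, alt_depth, float(rec.qual or 0.0)
                )
                (snps if key.is_snp else indels).append(call)
    return snps, indels


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def _sheet_path(raw: str, base: Path) -> Optional[Path]:
    raw = raw.strip()
    if raw in ("", "-"):
        return None
    p = Path(raw)
    if not p.is_absolute():
        p = base / p
    return p


def read_sample_sheet(path) -> list:
    """Read a batch-import sample sheet (tab-separated, fixed header).

    Relative file paths are resolved against the sheet's directory.  Rows
    referencing missing files, or repeating a sample_id, are errors; "-" or
    an empty cell means "no file of this kind".
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"sample sheet not found: {path}")
    base = path.parent
    rows: list = []
    seen: set = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty sample sheet")
        if tuple(header) != SAMPLE_SHEET_COLUMNS:
            raise ParseError(
                f"{path}: bad header {header!r}, expected "
                f"{list(SAMPLE_SHEET_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(SAMPLE_SHEET_COLUMNS):
                raise ParseError(
                    f"{path} line {lineno}: expected "
                    f"{len(SAMPLE_SHEET_COLUMNS)} columns, got {len(row)}"
                )
            sid = row[0].strip()
            if sid in seen:
                raise ValidationError(
                    f"{path} line {lineno}: duplicate sample_id {sid!r}"
                )
            seen.add(sid)
            try:
                sheet_row = SampleSheetRow(
                    sample_id=sid,
                    description=row[1],
                    platform=row[2],
                    format=row[3].strip(),
                    snp_path=_sheet_path(row[4], base),
                    indel_path=_sheet_path(row[5], base),
                )
            except ValidationError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            if sheet_row.snp_path is None and sheet_row.indel_path is None:
                raise ValidationError(
                    f"{path} line {lineno}: sample {sid!r} references no files"
                )
            for p in (sheet_row.snp_path, sheet_row.indel_path):
                if p is not None and not p.exists():
                    raise InputError(
                        f"{path} line {lineno}: referenced file missing: {p}"
                    )
            rows.append(sheet_row)
    return rows


def write_sample_sheet(path, rows: Iterable[SampleSheetRow]) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.sample_id,
                    r.description,
                    r.platform,
                    r.format,
                    "" if r.snp_path is None else str(r.snp_path),
                    "" if r.indel_path is None else str(r.indel_path),
                ]
            )


# ---------------------------------------------------------------------------
# gene models (refFlat/genePred dialect, optional trailing CDS-sequence column)
# ---------------------------------------------------------------------------

_REFFLAT_MIN_COLS = 11


def read_gene_models(path) -> list:
    """Read gene models from a refFlat-layout TSV.

    On-disk coordinates are 0-based half-open (genePred convention) and are
    converted to 1-based inclusive.  An optional 12th column carries the
    spliced CDS sequence in coding orientation.  ``cdsStart == cdsEnd``
    marks a noncoding model.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene model file not found: {path}")
    models: list = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < _REFFLAT_MIN_COLS:
                raise ParseError(
                    f"{path} line {lineno}: expected >= {_REFFLAT_MIN_COLS} "
                    f"columns, got {len(row)}"
                )
            try:
                gene, name, chrom, strand = row[0], row[1], row[2], row[3]
                tx_s, tx_e = int(row[4]), int(row[5])
                cds_s, cds_e = int(row[6]), int(row[7])
                exon_count = int(row[8])
                exon_starts = tuple(
                    int(x) for x in row[9].rstrip(",").split(",") if x
                )
                exon_ends = tuple(
                    int(x) for x in row[10].rstrip(",").split(",") if x
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from exc
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise ValidationError(
                    f"{path} line {lineno}: exonCount {exon_count} does not "
                    f"match exon lists ({len(exon_starts)}/{len(exon_ends)})"
                )
            cds_seq = None
            if len(row) > _REFFLAT_MIN_COLS and row[11].strip():
                cds_seq = row[11].strip().upper()
            noncoding = cds_s == cds_e
            try:
                model = GeneModel(
                    gene_symbol=gene,
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_s + 1,
                    tx_end=tx_e,
                    cds_start=None if noncoding else cds_s + 1,
                    cds_end=None if noncoding else cds_e,
                    exon_starts=tuple(s + 1 for s in exon_starts),
                    exon_ends=exon_ends,
                    cds_seq=cds_seq,
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from exc
            models.append(model)
    return models


def write_gene_models(path, models: Iterable[GeneModel]) -> None:
    """Write gene models in the refFlat dialect read by :func:`read_gene_models`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for m in models:
            if m.is_coding:
                cds_s, cds_e = m.cds_start - 1, m.cds_end
            else:
                cds_s = cds_e = m.tx_end  # genePred noncoding convention
            row = [
                m.gene_symbol,
                m.transcript_id,
                m.chrom,
                m.strand,
                m.tx_start - 1,
                m.tx_end,
                cds_s,
                cds_e,
                len(m.exon_starts),
                ",".join(str(s - 1) for s in m.exon_starts) + ",",
                ",".join(str(e) for e in m.exon_ends) + ",",
            ]
            if m.cds_seq is not None:
                row.append(m.cds_seq)
            writer.writerow(row)
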