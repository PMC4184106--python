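"""Download-free synthetic cohorts, gene fixtures, and the worked example.

Three generators:

* :func:`generate_cohort` — a seed-reproducible cohort of per-sample
  variant files with *planted* variants whose carrier sets are realized
  exactly (frequencies by deterministic rounding, carriers as the first k
  samples of a seed-fixed shuffle), so scenario truths support equality
  assertions rather than statistical ones.  Scenario presets
  (:func:`build_scenario`) cover the classic Mendelian and cohort designs:
  de novo in a trio, dominant and recessive family variants, and
  population-specific variants, each with decoys that violate exactly one
  filter condition.
* :func:`generate_gene_fixture` — random toy gene models (multi-exon, both
  strands, internally consistent CDS sequences) with dbSNP-style and
  score-style lookup tables covering a fraction of generated variants.
* :func:`build_wdm_fixture` — the distal-myopathy worked example: a store
  whose two in-group samples carry the 13 published candidate SNPs (loci,
  rs-ids, classes and gene symbols as printed; all heterozygous) plus two
  indel candidates, and whose filter-group samples carry decoys violating
  one condition each.  Allele and depth values at the candidate loci are
  fixture inventions (the published table lists no alleles or depths).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

from varvault.annotate import Annotator, DbsnpTable, ScoreTable, revcomp
from varvault.datastore import VariantStore, batch_import, init_store
from varvault.errors import ValidationError
from varvault.filter_engine import FilterSpec
from varvault.io_formats import (
    GeneModel,
    GenotypeCall,
    SampleSheetRow,
    VariantKey,
    read_gene_models,
    write_gene_models,
    write_internal_variants,
    write_sample_sheet,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with an exactly realized carrier set.

    ``carrier_spec`` is either an explicit list of sample ids, a mapping
    sample_id → zygosity, or a mapping population label → carrier
    frequency (realized by deterministic rounding).
    """

    variant: VariantKey
    carrier_spec: Union[Sequence, Mapping]
    zygosity_spec: str = "het"
    intended_scenario: str = "background"
    note: str = ""


@dataclass
class CohortScenario:
    populations: Dict[str, int]
    shared_variant_pool_size: int = 20
    per_sample_private_rate: float = 0.5
    planted: List[PlantedVariant] = field(default_factory=list)

    def __post_init__(self):
        if not self.populations:
            raise ValidationError("at least one population is required")
        for label, n in self.populations.items():
            if n <= 0:
                raise ValidationError(f"population {label!r} count must be > 0")
        if self.shared_variant_pool_size < 0:
            raise ValidationError("shared_variant_pool_size must be >= 0")
        if not (0.0 <= self.per_sample_private_rate <= 1.0):
            raise ValidationError("per_sample_private_rate must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.populations.values())


@dataclass
class CohortResult:
    outdir: Path
    sheet_path: Path
    manifest_path: Path
    sample_ids: List[str]
    labels: Dict[str, str]  # sample_id -> population label
    calls: Dict[str, Dict[VariantKey, str]]  # ground truth: sid -> key -> zyg
    planted_carriers: Dict[VariantKey, Dict[str, str]]


def _realize_carriers(
    planted: PlantedVariant,
    pop_members: Dict[str, List[str]],
    rng: random.Random,
) -> Dict[str, str]:
    spec = planted.carrier_spec
    if isinstance(spec, Mapping):
        values = list(spec.values())
        if values and all(isinstance(v, str) for v in values):
            return dict(spec)  # explicit sid -> zygosity
        carriers: Dict[str, str] = {}
        for label, freq in spec.items():
            if label not in pop_members:
                raise ValidationError(f"unknown population {label!r}")
            if not (0.0 <= float(freq) <= 1.0):
                raise ValidationError(
                    f"infeasible frequency {freq} for population {label!r}"
                )
            members = pop_members[label]
            k = int(round(float(freq) * len(members)))
            order = rng.sample(members, len(members))
            for sid in order[:k]:
                carriers[sid] = planted.zygosity_spec
        return carriers
    return {sid: planted.zygosity_spec for sid in spec}


def generate_cohort(
    scenario: CohortScenario, seed: int, outdir
) -> CohortResult:
    """Write a cohort (sample sheet, per-sample variant files, truth
    manifest) under ``outdir``.  Byte-identical for a fixed seed."""
    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pop_members: Dict[str, List[str]] = {}
    sample_ids: List[str] = []
    labels: Dict[str, str] = {}
    for label, n in scenario.populations.items():
        members = [f"{label}{i + 1:03d}" for i in range(n)]
        pop_members[label] = members
        sample_ids.extend(members)
        for sid in members:
            labels[sid] = label

    calls: Dict[str, Dict[VariantKey, str]] = {sid: {} for sid in sample_ids}
    manifest_rows: List[tuple] = []

    # shared background pool on chr21; random popularity per pool variant
    for j in range(scenario.shared_variant_pool_size):
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        key = VariantKey("chr21", 10_000_000 + 137 * j, ref, alt)
        n_carriers = rng.randint(1, max(1, len(sample_ids) // 2))
        carriers = rng.sample(sample_ids, n_carriers)
        for sid in carriers:
            calls[sid][key] = "hom" if rng.random() < 0.2 else "het"
        manifest_rows.append(
            (key, "background", "shared-pool", ";".join(sorted(carriers)), "")
        )

    # private background variants, at most one per sample
    for i, sid in enumerate(sample_ids):
        if rng.random() < scenario.per_sample_private_rate:
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            key = VariantKey("chr22", 20_000_000 + 211 * i, ref, alt)
            calls[sid][key] = "het"
            manifest_rows.append((key, "background", "private", sid, ""))

    planted_carriers: Dict[VariantKey, Dict[str, str]] = {}
    for planted in scenario.planted:
        carriers = _realize_carriers(planted, pop_members, rng)
        for sid, zyg in carriers.items():
            if sid not in calls:
                raise ValidationError(f"planted carrier {sid!r} not in cohort")
            calls[sid][planted.variant] = zyg
        planted_carriers[planted.variant] = carriers
        manifest_rows.append(
            (
                planted.variant,
                planted.intended_scenario,
                "planted",
                ";".join(f"{s}:{z}" for s, z in sorted(carriers.items())),
                planted.note,
            )
        )

    # write per-sample files + sheet
    sheet_rows = []
    any_indels = any(
        k.is_indel for per in calls.values() for k in per
    )
    for sid in sample_ids:
        per = calls[sid]
        snps = [
            GenotypeCall(k, z, 20, 10 if z == "het" else 20, 60.0)
            for k, z in sorted(per.items(), key=lambda kz: kz[0].sort_key())
            if k.is_snp
        ]
        indels = [
            GenotypeCall(k, z, 20, 10 if z == "het" else 20, 60.0)
            for k, z in sorted(per.items(), key=lambda kz: kz[0].sort_key())
            if k.is_indel
        ]
        snp_name = f"{sid}.snps.tsv"
        write_internal_variants(outdir / snp_name, snps)
        indel_name = None
        if any_indels:
            indel_name = f"{sid}.indels.tsv"
            write_internal_variants(outdir / indel_name, indels)
        # sheet paths are relative to the sheet itself, so a generated
        # cohort is byte-identical for a fixed seed wherever it is written
        sheet_rows.append(
            SampleSheetRow(
                sample_id=sid,
                description=f"synthetic cohort member ({labels[sid]})",
                platform="synthetic",
                format="internal",
                snp_path=Path(snp_name),
                indel_path=None if indel_name is None else Path(indel_name),
            )
        )
    sheet_path = outdir / "samples.tsv"
    write_sample_sheet(sheet_path, sheet_rows)

    manifest_path = outdir / "truth_manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tscenario\trole\tcarriers\tnote\n")
        for key, scen, role, carriers, note in manifest_rows:
            fh.write(
                f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{scen}\t"
                f"{role}\t{carriers}\t{note}\n"
            )

    return CohortResult(
        outdir=outdir,
        sheet_path=sheet_path,
        manifest_path=manifest_path,
        sample_ids=sample_ids,
        labels=labels,
        calls=calls,
        planted_carriers=planted_carriers,
    )


# ---------------------------------------------------------------------------
# scenario presets (de novo / dominant / recessive / population-specific)
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """A populated store, the filter spec that should recover the planted
    truth, and the planted/decoy keys for assertions."""

    store: VariantStore
    spec: FilterSpec
    planted_keys: Set[VariantKey]
    decoy_keys: Dict[VariantKey, str]
    cohort: CohortResult


SCENARIOS = ("de_novo", "dominant", "recessive", "population_specific")


def _import_cohort(cohort: CohortResult, store_path=":memory:") -> VariantStore:
    from varvault.io_formats import read_sample_sheet

    store = init_store(store_path, overwrite=True)
    sheet = read_sample_sheet(cohort.sheet_path)
    report = batch_import(store, sheet)
    if report.failed:
        raise ValidationError(f"cohort import failed: {report.failed}")
    return store


def build_scenario(
    kind: str, workdir, seed: int = 0, store_path=":memory:"
) -> ScenarioBundle:
    """Build one of the canonical filtering scenarios with planted truth
    and decoys, import it, and return the matching filter spec."""
    if kind == "de_novo":
        return _build_de_novo(workdir, seed, store_path)
    if kind == "dominant":
        return _build_dominant(workdir, seed, store_path)
    if kind == "recessive":
        return _build_recessive(workdir, seed, store_path)
    if kind == "population_specific":
        return _build_population(workdir, seed, store_path)
    raise ValidationError(f"unknown scenario {kind!r}; one of {SCENARIOS}")


def _build_de_novo(workdir, seed, store_path) -> ScenarioBundle:
    # T001 = child, T002 = mother, T003 = father, rest unrelated
    planted = PlantedVariant(
        VariantKey("chr3", 3_000_100, "A", "G"), ["T001"], "het", "de_novo"
    )
    decoys = {
        VariantKey("chr3", 3_000_200, "C", "T"): "inherited from mother "
        "(filter-group carrier)",
        VariantKey("chr3", 3_000_300, "G", "A"): "carried by a parent only "
        "(absent from the in-group)",
    }
    scenario = CohortScenario(
        populations={"T": 15},
        planted=[
            planted,
            PlantedVariant(
                VariantKey("chr3", 3_000_200, "C", "T"),
                ["T001", "T002"], "het", "decoy",
                note="inherited",
            ),
            PlantedVariant(
                VariantKey("chr3", 3_000_300, "G", "A"),
                ["T002"], "het", "decoy", note="parent-only",
            ),
        ],
    )
    cohort = generate_cohort(scenario, seed, workdir)
    store = _import_cohort(cohort, store_path)
    spec = FilterSpec(
        in_group=frozenset(["T001"]),
        filter_group=frozenset(s for s in cohort.sample_ids if s != "T001"),
        min_in_fraction=1.0,
        max_filter_count=0,
    )
    return ScenarioBundle(store, spec, {planted.variant}, decoys, cohort)


def _build_dominant(workdir, seed, store_path) -> ScenarioBundle:
    affected = ["D001", "D002", "D003"]
    planted = PlantedVariant(
        VariantKey("chr4", 4_000_100, "T", "C"), affected, "het", "dominant"
    )
    decoys = {
        VariantKey("chr4", 4_000_200, "A", "G"): "missing from one affected "
        "individual (in-group fraction below 100%)",
        VariantKey("chr4", 4_000_300, "C", "A"): "also carried by an "
        "unrelated sample (filter-group carrier)",
    }
    scenario = CohortScenario(
        populations={"D": 18},
        planted=[
            planted,
            PlantedVariant(
                VariantKey("chr4", 4_000_200, "A", "G"),
                ["D001", "D002"], "het", "decoy", note="partial in-group",
            ),
            PlantedVariant(
                VariantKey("chr4", 4_000_300, "C", "A"),
                affected + ["D005"], "het", "decoy", note="leaks to filter",
            ),
        ],
    )
    cohort = generate_cohort(scenario, seed, workdir)
    store = _import_cohort(cohort, store_path)
    spec = FilterSpec(
        in_group=frozenset(affected),
        filter_group=frozenset(
            s for s in cohort.sample_ids if s not in affected
        ),
        min_in_fraction=1.0,
        max_filter_count=0,
    )
    return ScenarioBundle(store, spec, {planted.variant}, decoys, cohort)


def _build_recessive(workdir, seed, store_path) -> ScenarioBundle:
    affected = ["R001", "R002"]
    relatives = ["R003", "R004"]  # possible healthy het carriers -> discard
    planted = PlantedVariant(
        VariantKey("chr5", 5_000_100, "G", "T"),
        {"R001": "hom", "R002": "hom", "R003": "het", "R004": "het"},
        "hom",
        "recessive",
    )
    decoys = {
        VariantKey("chr5", 5_000_200, "T", "G"): "affected individuals are "
        "only heterozygous (fails the hom-in-group requirement)",
        VariantKey("chr5", 5_000_300, "A", "C"): "homozygous in the affected "
        "but also carried by an unrelated sample",
    }
    scenario = CohortScenario(
        populations={"R": 16},
        planted=[
            planted,
            PlantedVariant(
                VariantKey("chr5", 5_000_200, "T", "G"),
                {"R001": "het", "R002": "het"}, "het", "decoy",
                note="het in affected",
            ),
            PlantedVariant(
                VariantKey("chr5", 5_000_300, "A", "C"),
                {"R001": "hom", "R002": "hom", "R005": "het"}, "hom", "decoy",
                note="leaks to filter",
            ),
        ],
    )
    cohort = generate_cohort(scenario, seed, workdir)
    store = _import_cohort(cohort, store_path)
    spec = FilterSpec(
        in_group=frozenset(affected),
        discard_group=frozenset(relatives),
        filter_group=frozenset(
            s for s in cohort.sample_ids
            if s not in affected and s not in relatives
        ),
        min_in_fraction=1.0,
        max_filter_count=0,
        zygosity_constraint="hom_in_group",
    )
    return ScenarioBundle(store, spec, {planted.variant}, decoys, cohort)


def _build_population(workdir, seed, store_path) -> ScenarioBundle:
    # thresholds at toy scale: >= 10% of the target population,
    # <= 1% of everyone else
    planted = PlantedVariant(
        VariantKey("chr6", 6_000_100, "C", "G"),
        {"A": 0.2, "B": 0.0, "C": 0.0},
        "het",
        "population_specific",
    )
    decoys = {
        VariantKey("chr6", 6_000_200, "G", "C"): "5% carrier frequency in "
        "the target population (below the 10% minimum)",
        VariantKey("chr6", 6_000_300, "T", "A"): "also carried in another "
        "population above the 1% ceiling",
    }
    scenario = CohortScenario(
        populations={"A": 40, "B": 40, "C": 40},
        planted=[
            planted,
            PlantedVariant(
                VariantKey("chr6", 6_000_200, "G", "C"),
                {"A": 0.05}, "het", "decoy", note="below min fraction",
            ),
            PlantedVariant(
                VariantKey("chr6", 6_000_300, "T", "A"),
                {"A": 0.2, "B": 0.025}, "het", "decoy", note="leaks to B",
            ),
        ],
    )
    cohort = generate_cohort(scenario, seed, workdir)
    store = _import_cohort(cohort, store_path)
    target = frozenset(s for s, l in cohort.labels.items() if l == "A")
    spec = FilterSpec(
        in_group=target,
        filter_group=frozenset(cohort.sample_ids) - target,
        min_in_fraction=0.10,
        max_filter_fraction=0.01,
    )
    return ScenarioBundle(store, spec, {planted.variant}, decoys, cohort)


# ---------------------------------------------------------------------------
# random gene fixtures
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


def random_cds(rng: random.Random, n_codons: int) -> str:
    """Random CDS: ATG, non-stop middle codons, one stop."""
    if n_codons < 3:
        raise ValidationError("CDS needs >= 3 codons")
    middle = [rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 2)]
    return "ATG" + "".join(middle) + rng.choice(sorted(_STOPS))


def random_gene_model(
    rng: random.Random,
    chrom: str,
    anchor: int,
    gene_symbol: str = "GENE",
    transcript_id: str = "tx",
    coding: bool = True,
    with_cds_seq: bool = False,
) -> GeneModel:
    """A random toy transcript: 1-3 exons, both strands, optional UTRs.

    With ``with_cds_seq`` the CDS span is trimmed to a multiple of 3 and a
    consistent random CDS sequence is attached.
    """
    n_exons = rng.randint(1, 3)
    exon_starts, exon_ends = [], []
    pos = anchor
    for _ in range(n_exons):
        length = rng.randint(30, 120)
        exon_starts.append(pos)
        exon_ends.append(pos + length - 1)
        pos = pos + length + rng.randint(20, 400)
    strand = rng.choice("+-")
    tx_start = exon_starts[0]
    tx_end = exon_ends[-1]
    if not coding:
        return GeneModel(
            gene_symbol, transcript_id, chrom, strand, tx_start, tx_end,
            None, None, tuple(exon_starts), tuple(exon_ends),
        )
    exonic = [
        p for s, e in zip(exon_starts, exon_ends) for p in range(s, e + 1)
    ]
    u5 = rng.randint(0, min(15, len(exonic) - 9))
    u3 = rng.randint(0, min(15, len(exonic) - 9 - u5))
    core = len(exonic) - u5 - u3
    u3 += core % 3  # trim to a codon multiple
    cds_start = exonic[u5]
    cds_end = exonic[len(exonic) - 1 - u3]
    cds_seq = None
    if with_cds_seq:
        n_codons = (len(exonic) - u5 - u3) // 3
        cds_seq = random_cds(rng, max(n_codons, 3))
        if n_codons < 3:  # widen exon 1 so the CDS fits at least 3 codons
            pad = (3 - n_codons) * 3
            exon_starts[0] -= pad
            tx_start -= pad
            exonic = [
                p for s, e in zip(exon_starts, exon_ends)
                for p in range(s, e + 1)
            ]
            cds_start = exonic[u5]
            cds_end = exonic[len(exonic) - 1 - u3]
    return GeneModel(
        gene_symbol, transcript_id, chrom, strand, tx_start, tx_end,
        cds_start, cds_end, tuple(exon_starts), tuple(exon_ends), cds_seq,
    )


def cds_base_at(model: GeneModel, pos: int) -> Optional[str]:
    """Genome-orientation reference base implied by the model's CDS
    sequence at a genomic position, or None outside the CDS exons."""
    if not model.is_coding or model.cds_seq is None:
        return None
    off = 0
    for s, e in model.exons:
        lo, hi = max(s, model.cds_start), min(e, model.cds_end)
        if lo > hi:
            continue
        if pos > hi:
            off += hi - lo + 1
        elif pos >= lo:
            off += pos - lo
            break
        else:
            return None
    else:
        return None
    if model.strand == "-":
        off = len(model.cds_seq) - 1 - off
        return revcomp(model.cds_seq[off])
    return model.cds_seq[off]


@dataclass
class GeneFixture:
    gene_models_path: Path
    dbsnp_path: Path
    scores_path: Path
    models: List[GeneModel]
    dbsnp: DbsnpTable
    scores: ScoreTable
    variants: List[VariantKey]  # example SNVs, CDS-consistent where exonic


def generate_gene_fixture(
    seed: int, outdir, n_genes: int = 6, dbsnp_fraction: float = 0.5,
    score_fraction: float = 0.5,
) -> GeneFixture:
    """Random toy genes on both strands plus dbSNP/score tables covering a
    stated fraction of the generated example variants."""
    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models: List[GeneModel] = []
    for i in range(n_genes):
        chrom = f"chr{1 + i % 3}"
        anchor = 1_000_000 + 50_000 * i
        coding = rng.random() > 0.2
        models.append(
            random_gene_model(
                rng, chrom, anchor, gene_symbol=f"TOY{i + 1}",
                transcript_id=f"TOY{i + 1}-tx1", coding=coding,
                with_cds_seq=coding,
            )
        )
    variants: List[VariantKey] = []
    for m in models:
        for _ in range(4):
            pos = rng.randint(m.tx_start - 1200, m.tx_end + 1200)
            ref = cds_base_at(m, pos) or rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            variants.append(VariantKey(m.chrom, pos, ref, alt))
    dbsnp_entries, score_entries = {}, {}
    for i, v in enumerate(variants):
        key = (v.chrom, v.pos, v.ref, v.alt)
        if rng.random() < dbsnp_fraction:
            dbsnp_entries[key] = (f"rs{900000 + i}", rng.random() < 0.5)
        if rng.random() < score_fraction:
            score_entries[key] = {
                "SIFT": round(rng.random(), 3),
                "GERP": round(rng.uniform(-2, 6), 2),
            }
    dbsnp = DbsnpTable(dbsnp_entries)
    scores = ScoreTable(score_entries)
    gene_models_path = outdir / "gene_models.tsv"
    dbsnp_path = outdir / "dbsnp.tsv"
    scores_path = outdir / "scores.tsv"
    write_gene_models(gene_models_path, models)
    dbsnp.write_tsv(dbsnp_path)
    scores.write_tsv(scores_path)
    return GeneFixture(
        gene_models_path, dbsnp_path, scores_path, models, dbsnp, scores,
        variants,
    )


# ---------------------------------------------------------------------------
# the worked-example fixture (distal myopathy screen)
# ---------------------------------------------------------------------------

# the 13 published candidate SNPs: locus, rs-id, display class, gene symbol
WDM_TABLE = [
    ("chr1", 16535487, "rs143314517", "Nonsynonymous", "ARHGEF19"),
    ("chr2", 69049697, "rs199643431", "Nonsynonymous", "ARHGAP25"),
    ("chr2", 70439862, "", "Nonsynonymous", "TIA1"),
    ("chr3", 10082028, "rs186545410", "Intronic", "FANCD2"),
    ("chr5", 114916295, "rs201468090", "Nonsynonymous", "TICAM2"),
    ("chr7", 70240520, "rs145296947", "Intronic", "AUTS2"),
    ("chr8", 113655825, "", "Intronic", "CSMD3"),
    ("chr10", 24833705, "rs1888656", "Intronic", "KIAA1217"),
    ("chr19", 1356844, "rs118122389", "Intronic", "MUM1"),
    ("chr19", 1370741, "rs199763366", "Synonymous", "MUM1"),
    ("chr19", 32131143, "", "Intergenic", ""),
    ("chr22", 45937910, "", "Intronic", "FBLN1"),
    ("chrX", 68424972, "", "Intergenic", ""),
]

# toy CDS used by the single-exon nonsynonymous genes:
# ATG GCT GCT TAA; the variant sits at CDS offset 4 (codon 2, position 1),
# C->T turning GCT (Ala) into GTT (Val).
_NONSYN_CDS = "ATGGCTGCTTAA"
_NONSYN_OFFSET = 4


def _nonsyn_gene(gene: str, chrom: str, pos: int, strand: str) -> tuple:
    """Single-exon coding gene placing ``pos`` at CDS offset 4; returns
    (model, genomic ref, genomic alt) for a nonsynonymous change."""
    if strand == "+":
        start = pos - _NONSYN_OFFSET
        end = start + len(_NONSYN_CDS) - 1
        ref, alt = "C", "T"
    else:
        end = pos + _NONSYN_OFFSET
        start = end - len(_NONSYN_CDS) + 1
        ref, alt = "G", "A"  # reverse complement of C->T
    model = GeneModel(
        gene, f"{gene}-tx1", chrom, strand, start, end, start, end,
        (start,), (end,), _NONSYN_CDS,
    )
    return model, ref, alt


def _intronic_gene(gene: str, chrom: str, pos: int) -> GeneModel:
    """Two-exon coding gene whose intron (far from both junctions)
    contains ``pos``."""
    e1 = (pos - 2000, pos - 1899)
    e2 = (pos + 1899, pos + 2000)
    cds_seq = "ATG" + "GCT" * 66 + "TAA"  # 204 bases = two 102-base exons
    return GeneModel(
        gene, f"{gene}-tx1", chrom, "+", e1[0], e2[1], e1[0], e2[1],
        (e1[0], e2[0]), (e1[1], e2[1]), cds_seq,
    )


def _mum1_gene() -> GeneModel:
    """Two-exon gene carrying both published MUM1 variants: one deep
    intronic, one synonymous (codon 4 GCT->GCA, Ala->Ala)."""
    # exon1 chr19:1356400-1356405 (6 CDS bases), exon2 1370736-1370747
    cds_seq = "ATGGCTCCAGCTAAATGA"  # 18 bases
    return GeneModel(
        "MUM1", "MUM1-tx1", "chr19", "+", 1356400, 1370747, 1356400, 1370747,
        (1356400, 1370736), (1356405, 1370747), cds_seq,
    )


@dataclass
class WdmFixture:
    store: VariantStore
    spec: FilterSpec  # SNP-table spec of the worked example
    indel_spec: FilterSpec  # same grouping against the indel table
    candidates: List[tuple]  # (VariantKey, rsid, display class, gene)
    indel_candidates: List[VariantKey]
    decoys: Dict[VariantKey, str]  # decoy -> violated condition
    outdir: Path
    annotator: Annotator


def build_wdm_fixture(
    workdir, n_filter_samples: int = 24, store_path=":memory:"
) -> WdmFixture:
    """Build the worked-example store.

    Two in-group samples (P1, P2) carry the 13 published candidate SNPs —
    all heterozygous, annotated via toy gene models so that locus, rs-id,
    class and gene symbol come out exactly as published — plus two
    (synthetic-locus) indel candidates.  ``n_filter_samples`` filter-group
    samples carry decoys that each violate exactly one filter condition.
    The returned spec is the published screen: both in-group samples must
    carry the variant, at most one filter-group sample may, and
    dbSNP-common variants are excluded.
    """
    if n_filter_samples < 20:
        raise ValidationError("the worked example uses >= 20 filter samples")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    models: List[GeneModel] = []
    candidate_keys: List[tuple] = []
    dbsnp_entries: Dict[tuple, Tuple[str, bool]] = {}
    mum1 = _mum1_gene()
    models.append(mum1)
    for chrom, pos, rsid, cls, gene in WDM_TABLE:
        if cls == "Nonsynonymous":
            strand = "-" if gene == "ARHGAP25" else "+"
            model, ref, alt = _nonsyn_gene(gene, chrom, pos, strand)
            models.append(model)
        elif cls == "Intronic":
            if gene != "MUM1":  # MUM1 model already built
                models.append(_intronic_gene(gene, chrom, pos))
            ref, alt = "A", "G"
        elif cls == "Synonymous":
            # MUM1 codon 4 (CDS offsets 9-11, "GCT"): T->A gives GCA (Ala)
            ref, alt = "T", "A"
        else:  # Intergenic
            ref, alt = "G", "C"
        key = VariantKey(chrom, pos, ref, alt)
        candidate_keys.append((key, rsid, cls, gene))
        if rsid:
            dbsnp_entries[(chrom, pos, ref, alt)] = (rsid, False)

    # two indel candidates; loci are synthetic (none are published)
    indel_candidates = [
        VariantKey("chr2", 70500000, "AG", "-"),
        VariantKey("chr17", 41200000, "-", "T"),
    ]

    # decoys, each violating exactly one condition
    decoy_shared = VariantKey("chr4", 5_000_000, "A", "G")
    decoy_common = VariantKey("chr6", 6_000_000, "C", "T")
    decoy_partial = VariantKey("chr9", 7_000_000, "G", "A")
    decoy_indel = VariantKey("chr2", 70500500, "T", "-")
    dbsnp_entries[(decoy_common.chrom, decoy_common.pos, decoy_common.ref,
                   decoy_common.alt)] = ("rs9990001", True)
    decoys = {
        decoy_shared: "carried by 2 filter-group samples (max_count=1)",
        decoy_common: "flagged dbSNP-common",
        decoy_partial: "carried by only one of the two in-group samples",
        decoy_indel: "indel private to a filter-group sample (no in-group "
        "carrier)",
    }

    # fixture score values for the two strongest candidates
    score_entries = {
        ("chr2", 70439862, "C", "T"): {"SIFT": 0.01, "GERP": 4.1},
        ("chr2", 69049697, "G", "A"): {"SIFT": 0.03, "PolyPhen2": 0.98},
    }

    gene_models_path = workdir / "gene_models.tsv"
    dbsnp_path = workdir / "dbsnp.tsv"
    scores_path = workdir / "scores.tsv"
    write_gene_models(gene_models_path, models)
    DbsnpTable(dbsnp_entries).write_tsv(dbsnp_path)
    ScoreTable(score_entries).write_tsv(scores_path)

    # per-sample calls; depths/qualities are fixture values
    def het(key: VariantKey) -> GenotypeCall:
        return GenotypeCall(key, "het", 14, 11, 92.0)

    calls: Dict[str, Dict[str, List[GenotypeCall]]] = {}
    in_group = ["P1", "P2"]
    for sid in in_group:
        snps = [het(k) for k, _r, _c, _g in candidate_keys]
        snps += [het(decoy_shared), het(decoy_common)]
        if sid == "P1":
            snps.append(het(decoy_partial))
        indels = [het(k) for k in indel_candidates]
        calls[sid] = {"snp": snps, "indel": indels}
    filter_ids = [f"F{i + 1:02d}" for i in range(n_filter_samples)]
    fancd2_key = next(
        k for k, _r, _c, g in candidate_keys if g == "FANCD2"
    )
    for i, sid in enumerate(filter_ids):
        snps = [
            het(VariantKey("chr11", 8_000_000 + 10 * i, "A", "C")),
            het(VariantKey("chr11", 8_000_005 + 10 * i, "T", "G")),
        ]
        if sid in ("F01", "F02"):
            snps.append(het(decoy_shared))
        if sid == "F03":
            # one filter-group carrier is allowed by max_count=1
            snps.append(het(fancd2_key))
        indels = [het(decoy_indel)] if sid == "F04" else []
        calls[sid] = {"snp": snps, "indel": indels}

    sheet_rows = []
    for sid in in_group + filter_ids:
        snp_name = f"{sid}.snps.tsv"
        indel_name = f"{sid}.indels.tsv"
        write_internal_variants(
            workdir / snp_name,
            sorted(calls[sid]["snp"], key=lambda c: c.variant.sort_key()),
        )
        write_internal_variants(
            workdir / indel_name,
            sorted(calls[sid]["indel"], key=lambda c: c.variant.sort_key()),
        )
        role = "affected" if sid in in_group else "control"
        sheet_rows.append(
            SampleSheetRow(sid, f"worked example ({role})", "synthetic",
                           "internal", Path(snp_name), Path(indel_name))
        )
    sheet_path = workdir / "samples.tsv"
    write_sample_sheet(sheet_path, sheet_rows)

    annotator = Annotator(
        models=read_gene_models(gene_models_path),
        dbsnp=DbsnpTable.from_tsv(dbsnp_path),
        scores=ScoreTable.from_tsv(scores_path),
    )
    store = init_store(store_path, overwrite=True)
    from varvault.io_formats import read_sample_sheet

    report = batch_import(store, read_sample_sheet(sheet_path), annotator)
    if report.failed:
        raise ValidationError(f"worked-example import failed: {report.failed}")

    spec = FilterSpec(
        in_group=frozenset(in_group),
        filter_group=frozenset(filter_ids),
        min_in_fraction=1.0,
        max_filter_count=1,
        variant_table="snp",
        exclude_dbsnp="common_only",
    )
    indel_spec = FilterSpec(
        in_group=frozenset(in_group),
        filter_group=frozenset(filter_ids),
        min_in_fraction=1.0,
        max_filter_count=1,
        variant_table="indel",
        exclude_dbsnp="common_only",
    )
    return WdmFixture(
        store=store,
        spec=spec,
        indel_spec=indel_spec,
        candidates=candidate_keys,
        indel_candidates=indel_candidates,
        decoys=decoys,
        outdir=workdir,
        annotator=annotator,
    )
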