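"""Annotator: region classes, coding effects, lookups, and the per-base oracle."""

import random

import pytest
from Bio.Seq import Seq

from _oracles import oracle_classify
from varvault.annotate import (
    Annotator,
    DbsnpTable,
    ScoreTable,
    annotate_variant,
    classify_coding_effect,
    classify_region,
    lookup_dbsnp,
    lookup_scores,
    revcomp,
)
from varvault.errors import ValidationError
from varvault.io_formats import GeneModel, VariantKey
from varvault.synthdata import cds_base_at, random_gene_model


def _single_exon_gene(chrom="chr1", start=1000, cds_seq="ATGGCTTAA",
                      strand="+", gene="G1"):
    end = start + len(cds_seq) - 1
    return GeneModel(
        gene, f"{gene}-tx1", chrom, strand, start, end, start, end,
        (start,), (end,), cds_seq,
    )


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def test_region_classes_of_a_two_exon_gene():
    # exon1 1000-1099, intron 1100-1499, exon2 1500-1599; CDS 1020-1579
    model = GeneModel(
        "G1", "G1-tx1", "chr1", "+", 1000, 1599, 1020, 1579,
        (1000, 1500), (1099, 1599),
    )
    cases = {
        1050: "exonic",
        1010: "UTR5",
        1590: "UTR3",
        1101: "splicing",  # 2 bp into the intron
        1498: "splicing",
        1300: "intronic",
        990: "upstream",
        1700: "downstream",
        500000: "intergenic",
    }
    for pos, expected in cases.items():
        region, gene, _ = classify_region(
            VariantKey("chr1", pos, "A", "G"), [model]
        )
        assert region == expected, f"pos {pos}"
        assert gene == ("" if expected == "intergenic" else "G1")


def test_exonic_wins_over_intronic_across_overlapping_genes():
    a = GeneModel("A", "A-tx", "chr1", "+", 1000, 2000, 1000, 2000,
                  (1000, 1900), (1100, 2000))
    b = GeneModel("B", "B-tx", "chr1", "+", 1400, 1700, 1400, 1700,
                  (1400,), (1700,))
    region, gene, hits = classify_region(
        VariantKey("chr1", 1500, "A", "G"), [a, b]
    )
    assert (region, gene) == ("exonic", "B")
    assert len(hits) == 2


def test_noncoding_model_reports_ncrna():
    nc = GeneModel("NC1", "NC1-tx", "chr1", "+", 1000, 1200, None, None,
                   (1000,), (1200,))
    region, gene, _ = classify_region(VariantKey("chr1", 1100, "A", "G"), [nc])
    assert (region, gene) == ("ncRNA", "NC1")


def test_splice_window_boundary():
    model = GeneModel("G", "tx", "chr1", "+", 1000, 1599, 1000, 1599,
                      (1000, 1500), (1099, 1599))
    for pos, expected, window in [
        (1101, "splicing", 2),
        (1102, "intronic", 2),
        (1104, "splicing", 5),
        (1101, "intronic", 0),
    ]:
        region, _, _ = classify_region(
            VariantKey("chr1", pos, "A", "G"), [model], splice_window=window
        )
        assert region == expected


def test_region_classification_matches_per_base_oracle():
    """1000 random toy models/variants against a painting-based scan."""
    rng = random.Random(20140103)
    for trial in range(250):
        models = []
        for g in range(rng.randint(1, 3)):
            anchor = rng.randint(5000, 9000)
            models.append(
                random_gene_model(
                    rng, "chr1", anchor, gene_symbol=f"G{g + 1}",
                    transcript_id=f"G{g + 1}-tx", coding=rng.random() > 0.25,
                )
            )
        window = rng.choice([0, 2, 5])
        for _ in range(4):
            pos = rng.randint(3000, 13000)
            key = VariantKey("chr1", pos, "A", "G")
            region, gene, _ = classify_region(key, models, window)
            exp_region, exp_gene = oracle_classify(pos, "chr1", models, window)
            assert (region, gene) == (exp_region, exp_gene), (
                f"trial {trial}, pos {pos}, window {window}"
            )


# ---------------------------------------------------------------------------
# coding effect
# ---------------------------------------------------------------------------

def test_snv_effect_examples():
    model = _single_exon_gene(cds_seq="ATGGCTTAA")
    # codon 2 position 1: GCT -> GTT = Ala -> Val
    eff, ctx = classify_coding_effect(
        VariantKey("chr1", 1004, "C", "T"), model
    )
    assert eff == "nonsynonymous"
    assert (ctx.codon_ref, ctx.codon_alt, ctx.aa_ref, ctx.aa_alt) == (
        "GCT", "GTT", "A", "V",
    )
    # codon 2 position 2: GCT -> GCA = Ala -> Ala
    eff, _ = classify_coding_effect(VariantKey("chr1", 1005, "T", "A"), model)
    assert eff == "synonymous"
    # codon 2 -> TAA stop (C at offset 4 -> A gives GAT? no: offset 3 G->T
    # makes TCT; build stopgain at codon 2 pos 0: GCT -> TCT is Ser, use
    # offset 4 C->A: GAT Asp). Direct stopgain: codon 3 TAA is already stop;
    # stoploss: TAA -> CAA at offset 6.
    eff, ctx = classify_coding_effect(VariantKey("chr1", 1006, "T", "C"), model)
    assert eff == "stoploss" and ctx.aa_ref == "*"


def test_stopgain_detection():
    model = _single_exon_gene(cds_seq="ATGTACTAA")  # codon 2 = TAC (Tyr)
    # TAC -> TAA at codon 2 position 2
    eff, ctx = classify_coding_effect(VariantKey("chr1", 1005, "C", "A"), model)
    assert eff == "stopgain" and ctx.aa_alt == "*"


def test_all_substitutions_match_translation_oracle():
    """Every possible substitution at every CDS position agrees with a
    direct whole-CDS translation comparison."""
    cds = "ATGGCTTGTCGATAA"
    model = _single_exon_gene(cds_seq=cds)
    for off in range(len(cds)):
        ref = cds[off]
        for alt in "ACGT":
            if alt == ref:
                continue
            mutated = cds[:off] + alt + cds[off + 1:]
            aa_ref = str(Seq(cds).translate())
            aa_alt = str(Seq(mutated).translate())
            ci = off // 3
            if aa_ref[ci] == aa_alt[ci]:
                expected = "synonymous"
            elif aa_alt[ci] == "*":
                expected = "stopgain"
            elif aa_ref[ci] == "*":
                expected = "stoploss"
            else:
                expected = "nonsynonymous"
            eff, _ = classify_coding_effect(
                VariantKey("chr1", 1000 + off, ref, alt), model
            )
            assert eff == expected, f"offset {off} {ref}>{alt}"


def test_strand_symmetry():
    """A minus-strand mirror gene gives identical effects for mirrored
    variants."""
    cds = "ATGGCTTGTCGATAA"
    plus = _single_exon_gene(chrom="chr1", start=1000, cds_seq=cds, strand="+")
    minus = GeneModel(
        "G1", "G1-txm", "chr1", "-", 1000, 1000 + len(cds) - 1,
        1000, 1000 + len(cds) - 1, (1000,), (1000 + len(cds) - 1,), cds,
    )
    for off in range(len(cds)):
        ref = cds[off]
        for alt in "ACGT":
            if alt == ref:
                continue
            eff_plus, _ = classify_coding_effect(
                VariantKey("chr1", 1000 + off, ref, alt), plus
            )
            # mirrored genomic position and complemented alleles
            mpos = 1000 + (len(cds) - 1 - off)
            eff_minus, _ = classify_coding_effect(
                VariantKey("chr1", mpos, revcomp(ref), revcomp(alt)), minus
            )
            assert eff_plus == eff_minus


@pytest.mark.parametrize(
    "key, expected",
    [
        (VariantKey("chr1", 1004, "AG", "-"), "frameshift"),
        (VariantKey("chr1", 1004, "AGC", "-"), "nonframeshift"),
        (VariantKey("chr1", 1004, "-", "T"), "frameshift"),
        (VariantKey("chr1", 1004, "-", "TTT"), "nonframeshift"),
        (VariantKey("chr1", 1004, "AT", "GCC"), "frameshift"),  # net +1
    ],
)
def test_indel_frame_rule(key, expected):
    model = _single_exon_gene(cds_seq="ATGGCTGCTGCTTAA")
    eff, ctx = classify_coding_effect(key, model)
    assert eff == expected and ctx is None


def test_coding_effect_outside_cds_is_contract_violation():
    model = _single_exon_gene(cds_seq="ATGGCTTAA")
    with pytest.raises(ValidationError):
        classify_coding_effect(VariantKey("chr1", 2000, "A", "G"), model)


def test_split_codon_across_exons():
    """CDS offsets accumulate across introns."""
    # exon1 1000-1004 (5 bases), exon2 1100-1103 (4 bases): CDS ATG GCT TAA
    cds = "ATGGCTTAA"
    model = GeneModel(
        "G", "tx", "chr1", "+", 1000, 1103, 1000, 1103,
        (1000, 1100), (1004, 1103), cds,
    )
    # position 1100 is CDS offset 5 -> codon 2 position 2 (T)
    eff, ctx = classify_coding_effect(VariantKey("chr1", 1100, "T", "A"), model)
    assert ctx.cds_offset == 5 and eff == "synonymous"  # GCT -> GCA


# ---------------------------------------------------------------------------
# lookups and composition
# ---------------------------------------------------------------------------

def test_dbsnp_lookup_is_allele_aware(tmp_path):
    p = tmp_path / "dbsnp.tsv"
    p.write_text(
        "chrom\tpos\tref\talt\trsid\tcommon_flag\n"
        "chr2\t69049697\tG\tA\trs199643431\t0\n"
    )
    assert lookup_dbsnp(VariantKey("chr2", 69049697, "G", "A"), p) == (
        "rs199643431", False,
    )
    assert lookup_dbsnp(VariantKey("chr2", 70439862, "C", "T"), p) == ("", False)
    # same position, different alt allele
    assert lookup_dbsnp(VariantKey("chr2", 69049697, "G", "T"), p) == ("", False)


def test_score_lookup(tmp_path):
    p = tmp_path / "scores.tsv"
    p.write_text(
        "chrom\tpos\tref\talt\tSIFT\tPolyPhen2\tGERP\n"
        "chr1\t100\tA\tG\t0.01\t.\t4.1\n"
    )
    assert lookup_scores(VariantKey("chr1", 100, "A", "G"), p) == {
        "SIFT": 0.01, "GERP": 4.1,
    }
    assert lookup_scores(VariantKey("chr1", 200, "A", "G"), p) == {}
    assert lookup_scores(VariantKey("chr1", 100, "AT", "-"), p) == {}


def test_annotate_variant_composition():
    model = _single_exon_gene(chrom="chr2", start=70439858,
                              cds_seq="ATGGCTGCTTAA", gene="TIA1")
    dbsnp = DbsnpTable({("chr2", 200, "A", "G"): ("rs1", True)})
    scores = ScoreTable({("chr2", 70439862, "C", "T"): {"SIFT": 0.01}})
    res = annotate_variant(
        VariantKey("chr2", 70439862, "C", "T"), [model], dbsnp, scores
    )
    assert (res.region_class, res.effect_class, res.gene_symbol) == (
        "exonic", "nonsynonymous", "TIA1",
    )
    assert res.rsid == "" and not res.is_dbsnp_common
    assert res.scores == {"SIFT": 0.01}

    res2 = annotate_variant(VariantKey("chr2", 200, "A", "G"), [model], dbsnp)
    assert (res2.region_class, res2.effect_class, res2.gene_symbol) == (
        "intergenic", "none", "",
    )
    assert (res2.rsid, res2.is_dbsnp_common) == ("rs1", True)

    # exonic 1-bp deletion -> frameshift
    res3 = annotate_variant(VariantKey("chr2", 70439862, "C", "-"), [model])
    assert (res3.region_class, res3.effect_class) == ("exonic", "frameshift")


def test_annotation_determinism():
    rng = random.Random(5)
    fixture_models = [
        random_gene_model(rng, "chr1", 5000 + 3000 * i, f"G{i}", f"G{i}-tx",
                          with_cds_seq=True)
        for i in range(3)
    ]
    ann1 = Annotator(fixture_models)
    ann2 = Annotator(fixture_models)
    for pos in range(4000, 12000, 37):
        m = fixture_models[0]
        ref = cds_base_at(fixture_models[0], pos) or "A"
        alt = "G" if ref != "G" else "C"
        key = VariantKey("chr1", pos, ref, alt)
        assert ann1.annotate(key) == ann2.annotate(key)


def test_multi_transcript_severity_max():
    """With overlapping transcripts the most severe effect is reported."""
    cds_a = "ATGTACTAA"  # codon 2 TAC: C->A gives stopgain
    a = _single_exon_gene(chrom="chr1", start=1000, cds_seq=cds_a, gene="A")
    # transcript B overlaps in a different frame: the same genomic change
    # hits its codon CAA -> AAA (Gln -> Lys, merely nonsynonymous)
    b = GeneModel(
        "B", "B-tx", "chr1", "+", 999, 1007, 999, 1007, (999,), (1007,),
        "ATGGCCCAA",
    )
    res = annotate_variant(VariantKey("chr1", 1005, "C", "A"), [a, b])
    assert res.effect_class == "stopgain"
    assert res.gene_symbol == "A"
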