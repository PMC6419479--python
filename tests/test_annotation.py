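"""Strand-aware typing, region precedence, and codon-level consequences."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rddscan import (
    GeneIndex,
    GeneModel,
    annotate_candidates,
    classify_region,
    coding_consequence,
    strand_correct_type,
)
from rddscan.config import COMPLEMENT
from rddscan.rdd_detection import RDDCandidate


# ---------------------------------------------------------------------------
# strand_correct_type
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,strands,expected",
    [
        ("A", "G", {"+"}, "A-to-G"),
        ("T", "C", {"-"}, "A-to-G"),
        ("C", "T", {"+"}, "C-to-T"),
        ("G", "A", {"-"}, "C-to-T"),
        ("A", "G", {"+", "-"}, "unassigned"),  # bidirectional transcription
        ("A", "G", set(), "unassigned"),  # untranscribed
    ],
)
def test_strand_corrected_typing(ref, alt, strands, expected):
    assert strand_correct_type(ref, alt, strands) == expected


def test_identical_alleles_rejected():
    with pytest.raises(ValueError):
        strand_correct_type("A", "A", {"+"})


@given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
def test_minus_strand_typing_equals_complemented_plus_typing(ref, alt):
    if ref == alt:
        return
    assert strand_correct_type(ref, alt, {"-"}) == strand_correct_type(
        COMPLEMENT[ref], COMPLEMENT[alt], {"+"}
    )


# ---------------------------------------------------------------------------
# classify_region
# ---------------------------------------------------------------------------


def _coding_model(gene="gA", tx="tA", strand="+", offset=0):
    return GeneModel(
        gene_id=gene, transcript_id=tx, chrom="chr1", strand=strand,
        exons=[(offset + 1, offset + 100), (offset + 201, offset + 300)],
        cds=[(offset + 31, offset + 100), (offset + 201, offset + 262)],  # 132 bp
        utr5=[(offset + 1, offset + 30)],
        utr3=[(offset + 263, offset + 300)],
    )


def test_region_precedence_and_gene_support():
    gene_a = _coding_model()  # intron 101-200
    gene_b = GeneModel(  # CDS covering gene A's intron
        gene_id="gB", transcript_id="tB", chrom="chr1", strand="-",
        exons=[(120, 180)], cds=[(120, 180)],
    )
    index = GeneIndex([gene_a, gene_b])
    region, genes = classify_region("chr1", 150, index)
    assert region == "exonic" and genes == ["gB"]  # exonic beats intronic
    assert classify_region("chr1", 50, index) == ("exonic", ["gA"])
    assert classify_region("chr1", 10, index) == ("UTR5", ["gA"])
    assert classify_region("chr1", 270, index) == ("UTR3", ["gA"])
    assert classify_region("chr1", 190, index) == ("intronic", ["gA"])
    assert classify_region("chr1", 5000, index) == ("intergenic", [])


def test_splicing_class_wins_over_intronic_and_utr():
    model = _coding_model()
    index = GeneIndex([model])
    # intronic base 2 bp from the junction at 101
    assert classify_region("chr1", 103, index, splice_window_bp=4)[0] == "splicing"
    assert classify_region("chr1", 106, index, splice_window_bp=4)[0] == "intronic"


def test_ncrna_exon_class():
    nc = GeneModel(
        gene_id="gN", transcript_id="tN", chrom="chr1", strand="+",
        exons=[(10, 60)], biotype="ncRNA",
    )
    assert classify_region("chr1", 20, GeneIndex([nc])) == ("ncRNA", ["gN"])


# ---------------------------------------------------------------------------
# coding_consequence
# ---------------------------------------------------------------------------


def _single_codon_model(strand="+"):
    return GeneModel(
        gene_id="g", transcript_id="t", chrom="chr1", strand=strand,
        exons=[(1, 6)], cds=[(1, 6)],
    )


def test_tyrosine_to_cysteine_recoding():
    # TAC -> TGC, the recoding signature seen in BLCAP-like substrates
    seq = "TACTAA"
    cons, aa = coding_consequence(2, "A", "G", _single_codon_model(), seq)
    assert (cons, aa) == ("nonsynonymous", "Y→C")


def test_lysine_to_arginine_recoding():
    # AAA -> AGA, the NEIL1-like K/R site
    seq = "AAATAA"
    cons, aa = coding_consequence(2, "A", "G", _single_codon_model(), seq)
    assert (cons, aa) == ("nonsynonymous", "K→R")


def test_synonymous_third_position_edit():
    seq = "GGATAA"
    cons, aa = coding_consequence(3, "A", "G", _single_codon_model(), seq)
    assert (cons, aa) == ("synonymous", None)


def test_stop_gain_and_stop_loss():
    cons, aa = coding_consequence(3, "G", "A", _single_codon_model(), "TGGTAA")
    assert (cons, aa) == ("stopgain", "W→*")
    cons, aa = coding_consequence(1, "T", "C", _single_codon_model(), "TAATAA")
    assert (cons, aa) == ("stoploss", "*→Q")


def test_minus_strand_codon_built_in_transcript_orientation():
    # sense CDS = TAC TAA; genomic plus strand is its reverse complement
    sense = "TACTAA"
    genomic = sense[::-1].translate(str.maketrans("ACGT", "TGCA"))
    model = _single_codon_model(strand="-")
    # sense position 2 (the A of TAC) sits at genomic position 5: edit T>C there
    cons, aa = coding_consequence(5, COMPLEMENT["A"], COMPLEMENT["G"], model, genomic)
    assert (cons, aa) == ("nonsynonymous", "Y→C")


def test_position_outside_cds_is_an_error():
    with pytest.raises(ValueError, match="not in the CDS"):
        coding_consequence(7, "A", "G", _single_codon_model(), "TACTAAA")


# ---------------------------------------------------------------------------
# annotate_candidates
# ---------------------------------------------------------------------------


def test_candidates_gain_type_region_and_consequence():
    model = _coding_model()
    index = GeneIndex([model])
    # reference with an ORF-ish CDS is irrelevant here; supply real bases
    seq = "A" * 400
    cand = RDDCandidate(
        chrom="chr1", pos=32, ref_base="A", alt_base="G",
        rna_alt_reads=12, rna_total_reads=30, edit_ratio=0.4,
        dna_depth=25, fs=0.0, site_qual=150.0,
    )
    (ann,) = annotate_candidates([cand], index, {"chr1": seq})
    assert ann.rdd_type == "A-to-G"
    assert ann.region == "exonic"
    assert ann.gene_ids == ["gA"]
    assert ann.consequence in ("synonymous", "nonsynonymous", "stopgain")
    intergenic = RDDCandidate(
        chrom="chr1", pos=5000, ref_base="A", alt_base="G",
        rna_alt_reads=12, rna_total_reads=30, edit_ratio=0.4,
        dna_depth=25, fs=0.0, site_qual=150.0,
    )
    (ann2,) = annotate_candidates([intergenic], index, {"chr1": seq})
    assert ann2.rdd_type == "unassigned"
    assert ann2.region == "intergenic" and ann2.consequence == "n/a"
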