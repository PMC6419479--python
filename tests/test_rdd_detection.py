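"""Filter cascade behaviour: examples, error paths, and monotonicity."""

import math

import pytest

from rddscan import FilterConfig, GeneIndex, GeneModel, RepeatMask, detect_rdds, edit_ratio
from rddscan.io_formats import BedRecord
from rddscan.rdd_detection import (
    read_candidate_table,
    splice_proximity,
    write_candidate_table,
)

from conftest import make_site


def test_edit_ratio_is_exact_division():
    assert edit_ratio(12, 30) == pytest.approx(0.4)
    assert edit_ratio(3, 30) == pytest.approx(0.10)
    assert edit_ratio(29, 30) == pytest.approx(0.9667, abs=5e-5)
    with pytest.raises(ValueError):
        edit_ratio(1, 0)
    with pytest.raises(ValueError):
        edit_ratio(5, 3)


@pytest.fixture
def two_exon_index():
    model = GeneModel(
        gene_id="g1", transcript_id="t1", chrom="chr1", strand="+",
        exons=[(1, 100), (201, 300)],  # intron spans 101-200
        cds=[(1, 100), (201, 300)],
    )
    return GeneIndex([model])


def test_splice_proximity_measures_distance_to_intron_ends(two_exon_index):
    assert splice_proximity(103, two_exon_index, "chr1") == 2
    assert splice_proximity(106, two_exon_index, "chr1") == 5
    assert splice_proximity(101, two_exon_index, "chr1") == 0
    assert splice_proximity(200, two_exon_index, "chr1") == 0
    assert splice_proximity(198, two_exon_index, "chr1") == 2
    assert math.isinf(splice_proximity(5000, two_exon_index, "chr1"))


def _detect_single(dna_site, rna_site, config=None, **kw):
    res = detect_rdds([dna_site], [rna_site], config, **kw)
    assert len(res.candidates) == 1
    return res.candidates[0]


def test_clean_editing_site_passes_all_filters():
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="A", A=18, G=12)
    cand = _detect_single(dna, rna)
    assert cand.passed
    assert cand.alt_base == "G"
    assert cand.edit_ratio == pytest.approx(0.4)


def test_shallow_rna_coverage_fails_min_rna_reads():
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="A", A=1, G=8)  # 9 RNA reads
    cand = _detect_single(dna, rna)
    assert "min_rna_reads" in cand.filters_failed


def test_heterozygous_dna_is_rejected():
    dna = make_site(ref="A", A=18, G=2)
    rna = make_site(ref="A", A=18, G=12)
    cand = _detect_single(dna, rna)
    assert "dna_not_homozygous" in cand.filters_failed


def test_low_mapping_quality_fraction_fails():
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="A", A=18, G=12, frac_mapq_ge=0.9)
    assert "min_mapq" in _detect_single(dna, rna).filters_failed


def test_low_mean_base_quality_fails():
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="A", A=18, G=12, mean_baseq=15.0)
    assert "min_baseq" in _detect_single(dna, rna).filters_failed


def test_strand_biased_alt_reads_fail_fisher_filter():
    dna = make_site(ref="A", A=40)
    rna = make_site(ref="A", A=(20, 20), G=(15, 0))
    cand = _detect_single(dna, rna)
    assert "max_fs" in cand.filters_failed
    assert cand.fs > 30


def test_multiallelic_rna_site_is_flagged():
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="A", A=14, G=10, C=4)
    assert "multiallelic" in _detect_single(dna, rna).filters_failed


def test_intronic_site_near_junction_is_filtered(two_exon_index):
    dna = make_site(pos=103, ref="A", A=20)
    rna = make_site(pos=103, ref="A", A=18, G=12)
    cand = _detect_single(dna, rna, gene_index=two_exon_index)
    assert "splice_window" in cand.filters_failed
    # an exonic site equally close to the junction is untouched
    dna2 = make_site(pos=99, ref="A", A=20)
    rna2 = make_site(pos=99, ref="A", A=18, G=12)
    cand2 = _detect_single(dna2, rna2, gene_index=two_exon_index)
    assert "splice_window" not in cand2.filters_failed


def test_repeat_overlap_filtered_only_when_enabled():
    mask = RepeatMask([BedRecord(chrom="chr1", start=90, end=110)])
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="A", A=18, G=12)
    cand = _detect_single(dna, rna, FilterConfig(), repeats=mask)
    assert cand.filters_failed == ["repeat"]
    cand2 = _detect_single(dna, rna, FilterConfig(exclude_repeats=False), repeats=mask)
    assert cand2.passed


def test_conflicting_reference_bases_raise():
    dna = make_site(ref="A", A=20)
    rna = make_site(ref="C", C=20, G=5)
    with pytest.raises(ValueError, match="conflicting reference"):
        detect_rdds([dna], [rna])


def test_unsorted_stream_raises():
    dna = [make_site(pos=10, A=20), make_site(pos=5, A=20)]
    rna = [make_site(pos=5, A=18, G=12), make_site(pos=10, A=18, G=12)]
    with pytest.raises(ValueError, match="not sorted"):
        detect_rdds(dna, rna)


def test_rna_only_or_dna_only_positions_are_skipped():
    dna = [make_site(pos=5, A=20), make_site(pos=10, A=20)]
    rna = [make_site(pos=10, A=18, G=12), make_site(pos=15, A=18, G=12)]
    res = detect_rdds(dna, rna)
    assert res.n_positions_evaluated == 1
    assert [c.pos for c in res.candidates] == [10]


def test_tightening_thresholds_never_adds_pass_candidates(small_dataset, small_index):
    ds = small_dataset
    base_cfg = FilterConfig(genotyping_error_rate=0.001)
    base = {
        c.key()
        for c in detect_rdds(
            ds.dna, ds.rna_replicates[0], base_cfg, gene_index=small_index
        ).passing
    }
    stricter = [
        FilterConfig(genotyping_error_rate=0.001, min_rna_reads=20),
        FilterConfig(genotyping_error_rate=0.001, min_alt_reads=6),
        FilterConfig(genotyping_error_rate=0.001, min_site_qual=300),
        FilterConfig(
            genotyping_error_rate=0.001, edit_ratio_min=0.25, edit_ratio_max=0.75
        ),
    ]
    for cfg in stricter:
        tighter = {
            c.key()
            for c in detect_rdds(
                ds.dna, ds.rna_replicates[0], cfg, gene_index=small_index
            ).passing
        }
        assert tighter <= base


def test_simulated_het_snvs_never_pass(small_dataset, small_index):
    ds = small_dataset
    het_positions = {(h.chrom, h.pos) for h in ds.het_snvs}
    cfg = FilterConfig(genotyping_error_rate=0.001)
    for rep in ds.rna_replicates:
        res = detect_rdds(ds.dna, rep, cfg, gene_index=small_index)
        for c in res.passing:
            assert (c.chrom, c.pos) not in het_positions


def test_candidate_table_round_trip(tmp_path, small_dataset):
    ds = small_dataset
    res = detect_rdds(ds.dna, ds.rna_replicates[0], FilterConfig())
    path = str(tmp_path / "cand.tsv")
    write_candidate_table(res.candidates, path)
    back = read_candidate_table(path)
    assert [(c.key(), tuple(c.filters_failed)) for c in back] == [
        (c.key(), tuple(c.filters_failed)) for c in res.candidates
    ]
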