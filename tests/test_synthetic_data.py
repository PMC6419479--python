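"""Generator behaviour: determinism, structure, truth bookkeeping, sampling."""

import filecmp

import numpy as np
import pytest

from rddscan import (
    SimulationConfig,
    generate_reference,
    place_het_snvs,
    place_truth_sites,
    simulate_dataset,
    simulate_pileups,
    strand_correct_type,
)
from rddscan.config import COMPLEMENT
from rddscan.synthetic_data import SizingError, TruthSite


def tiny_config(**kw):
    defaults = dict(
        seed=5,
        n_chroms=1,
        chrom_length=10_000,
        n_genes=4,
        n_edit_sites=12,
        n_replicates=2,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_fixed_seed_reproduces_every_file_byte_for_byte(tmp_path):
    cfg = tiny_config()
    a = simulate_dataset(cfg, str(tmp_path / "a"))
    b = simulate_dataset(cfg, str(tmp_path / "b"))
    for key in ("reference", "annotation", "truth", "dna_pileup"):
        assert filecmp.cmp(a.paths[key], b.paths[key], shallow=False), key
    for pa, pb in zip(a.paths["rna_pileups"], b.paths["rna_pileups"]):
        assert filecmp.cmp(pa, pb, shallow=False)


def test_genome_without_genes_is_valid(tmp_path):
    cfg = tiny_config(n_genes=0, n_edit_sites=0)
    reference, models = generate_reference(cfg)
    assert models == []
    assert set(reference) == {"chr1"}
    assert len(reference["chr1"]) == cfg.chrom_length
    assert set(reference["chr1"]) <= set("ACGT")


def test_gene_models_parse_back_with_expected_structure(tmp_path):
    from rddscan import read_gff3, write_gff3

    cfg = tiny_config(seed=1, n_genes=4, exons_per_gene=(3, 3))
    _, models = generate_reference(cfg)
    path = str(tmp_path / "genes.gff3")
    write_gff3(models, path)
    parsed = read_gff3(path)
    assert len(parsed) == 4
    for m in parsed:
        assert len(m.exons) == 3
        starts = [s for s, _ in m.exons]
        ends = [e for _, e in m.exons]
        assert starts == sorted(starts) and ends == sorted(ends)
        assert all(e >= s for s, e in m.exons)
        assert len(m.introns()) == 2  # >=1 intron whenever exons_per_gene > 1
    # round trip: write -> read -> equal
    key = lambda m: (
        m.gene_id, m.transcript_id, m.chrom, m.strand,
        m.exons, m.cds, m.utr5, m.utr3, m.biotype,
    )
    assert sorted(map(key, parsed)) == sorted(map(key, models))


def test_coding_models_have_orf_like_cds():
    _, models = generate_reference(tiny_config(seed=9, n_genes=6, chrom_length=25_000))
    coding = [m for m in models if m.is_coding]
    assert coding, "expected some protein-coding models"
    for m in coding:
        assert m.cds_length() % 3 == 0
        assert all(s <= e for s, e in m.cds)


def test_truth_sites_unique_and_within_bounds():
    cfg = tiny_config(n_edit_sites=100, chrom_length=30_000, n_genes=8)
    reference, models = generate_reference(cfg)
    sites = place_truth_sites(cfg, models, reference)
    assert len(sites) == 100
    positions = {(s.chrom, s.pos) for s in sites}
    assert len(positions) == 100  # no duplicates
    for s in sites:
        assert 1 <= s.pos <= len(reference[s.chrom])
        assert s.edited_base != s.ref_base


@pytest.mark.parametrize("strand,expected", [("+", ("A", "G")), ("-", ("T", "C"))])
def test_genomic_substitution_is_sense_type_complemented_on_minus(strand, expected):
    cfg = tiny_config(
        n_edit_sites=30,
        chrom_length=30_000,
        n_genes=10,
        edit_type_weights={"A-to-G": 1.0},
        ncrna_fraction=0.0,
        region_weights={"exonic": 1.0},
    )
    reference, models = generate_reference(cfg)
    sites = place_truth_sites(cfg, models, reference)
    on_strand = [s for s in sites if s.strand == strand]
    assert on_strand, f"no sites landed on {strand} transcripts"
    for s in on_strand:
        assert (s.genomic_ref, s.genomic_alt) == expected
        # the genomic ref must be the actual reference base
        assert reference[s.chrom][s.pos - 1] == s.genomic_ref


def test_truth_sense_type_round_trips_through_strand_correction():
    # closes the loop with the annotation module
    cfg = tiny_config(n_edit_sites=40, chrom_length=30_000, n_genes=10)
    reference, models = generate_reference(cfg)
    for s in place_truth_sites(cfg, models, reference):
        strands = {s.strand} if s.transcript_id else {"+"}
        assert (
            strand_correct_type(s.genomic_ref, s.genomic_alt, strands)
            == f"{s.ref_base}-to-{s.edited_base}"
        )


def test_error_free_rna_matches_reference_everywhere():
    cfg = tiny_config(error_rate=0.0, het_snv_rate=0.0, n_edit_sites=0)
    reference, models = generate_reference(cfg)
    rna = simulate_pileups(reference, models, [], [], cfg, "RNA", "r1", 1)
    assert rna
    for site in rna:
        assert site.count(site.ref_base) == site.depth
        assert reference[site.chrom][site.pos - 1] == site.ref_base


def test_fully_edited_site_shows_only_edited_base():
    cfg = tiny_config(error_rate=0.0, het_snv_rate=0.0, n_genes=0, n_edit_sites=0)
    reference, _ = generate_reference(cfg)
    pos = 500
    truth = TruthSite(
        chrom="chr1",
        pos=pos,
        ref_base=reference["chr1"][pos - 1],
        edited_base="G" if reference["chr1"][pos - 1] != "G" else "A",
        strand="+",
        transcript_id=None,
        true_edit_ratio=1.0,
        region_class="intergenic",
    )
    rna = simulate_pileups(reference, [], [truth], [], cfg, "RNA", "r1", 1)
    at = {s.pos: s for s in rna}[pos]
    assert at.count(truth.genomic_alt) == at.depth > 0


def test_observed_edit_fraction_is_binomial():
    """1000 half-edited sites at depth 30: the pooled edited fraction must sit
    within 3 standard errors of 0.5."""
    cfg = tiny_config(
        error_rate=0.0, het_snv_rate=0.0, n_genes=0, n_edit_sites=0,
        rna_depth_mean=30.0, chrom_length=2000,
    )
    reference, _ = generate_reference(cfg)
    truths = [
        TruthSite(
            chrom="chr1", pos=p, ref_base=reference["chr1"][p - 1],
            edited_base=COMPLEMENT[reference["chr1"][p - 1]], strand="+",
            transcript_id=None, true_edit_ratio=0.5, region_class="intergenic",
        )
        for p in range(1, 1001)
    ]
    rna = simulate_pileups(reference, [], truths, [], cfg, "RNA", "r1", 1)
    by_pos = {s.pos: s for s in rna}
    edited = total = 0
    for t in truths:
        s = by_pos.get(t.pos)
        if s is None:
            continue
        edited += s.count(t.genomic_alt)
        total += s.depth
    frac = edited / total
    se = np.sqrt(0.25 / total)
    assert abs(frac - 0.5) < 3 * se


def test_het_snvs_show_in_both_samples_and_avoid_truth(small_dataset):
    ds = small_dataset
    truth_positions = {(t.chrom, t.pos) for t in ds.truth_sites}
    dna_at = {(s.chrom, s.pos): s for s in ds.dna}
    assert ds.het_snvs
    for h in ds.het_snvs:
        assert (h.chrom, h.pos) not in truth_positions
        site = dna_at[(h.chrom, h.pos)]
        if site.depth >= 10:
            assert site.count(h.alt_base) > 0  # het visible in DNA


def test_sizing_errors_are_explicit():
    with pytest.raises(SizingError):
        generate_reference(tiny_config(n_genes=30, chrom_length=2000))
    cfg = tiny_config(n_edit_sites=50_000)
    reference, models = generate_reference(cfg)
    with pytest.raises(SizingError):
        place_truth_sites(cfg, models, reference)


def test_het_rate_zero_gives_no_snvs():
    cfg = tiny_config(het_snv_rate=0.0)
    reference, _ = generate_reference(cfg)
    assert place_het_snvs(cfg, reference) == []
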