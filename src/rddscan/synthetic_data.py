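"""Synthetic genomes, gene models and matched DNA/RNA pileups with known truth.

The generator emulates the statistical structure the detection cascade
assumes, at toy scale:

* a random diploid reference with non-overlapping genes (exons/introns,
  CDS and UTRs on protein-coding transcripts, ~50/50 strand assignment);
  every CDS is a clean open reading frame (ATG, sense codons, single stop);
* heterozygous DNA SNVs at a configurable per-bp rate — visible in both the
  DNA and RNA samples, so the "heterozygous at DNA level is not an RDD"
  rejection path is exercised;
* injected editing events with chosen sense-strand type and per-site edit
  ratio; on minus-strand transcripts the genomic substitution is the reverse
  complement of the drawn type;
* per-site, per-strand pileup counts: depth ~ Poisson, edited-read counts ~
  Binomial(depth, edit ratio), uniform substitution sequencing error, reads
  split ~50/50 across strands. RNA coverage spans transcribed intervals
  (pre-mRNA, so introns are covered) plus a configurable fraction of
  intergenic background, plus small windows around intergenic truth sites
  (modelling unannotated transcription, which is where intergenic RDDs come
  from).

Everything is deterministic for a fixed config seed. Truth sites are never
placed on het-SNV positions, nor on intronic positions within the splice
buffer of a junction: the generator's contract is that a covered truth site
is recoverable, and junction-adjacent intronic sites are removed
deterministically by design.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import COMPLEMENT, SimulationConfig
from .io_formats import (
    BASES,
    BedRecord,
    GeneModel,
    PileupSite,
    write_bed,
    write_fasta,
    write_gff3,
    write_pileup_table,
)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOP_CODONS
)
#: RNA coverage window, in bp, opened around each intergenic truth site
_INTERGENIC_TRUTH_WINDOW = 30


class SizingError(ValueError):
    """Raised when the requested genes/sites do not fit the toy genome."""


@dataclass
class TruthSite:
    """Ground-truth editing event, recorded in the transcript sense alphabet."""

    chrom: str
    pos: int  # 1-based
    ref_base: str  # sense strand of the host transcript ("+" if intergenic)
    edited_base: str  # sense strand
    strand: str
    transcript_id: Optional[str]
    true_edit_ratio: float
    region_class: str

    @property
    def genomic_ref(self) -> str:
        return self.ref_base if self.strand == "+" else COMPLEMENT[self.ref_base]

    @property
    def genomic_alt(self) -> str:
        return self.edited_base if self.strand == "+" else COMPLEMENT[self.edited_base]

    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.genomic_ref, self.genomic_alt)


@dataclass
class HetSNV:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str


# ---------------------------------------------------------------------------
# Reference + gene models
# ---------------------------------------------------------------------------


def generate_reference(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], List[GeneModel]]:
    """Generate chromosome sequences and non-overlapping gene models.

    Deterministic for a fixed seed. Genes are distributed round-robin across
    chromosomes and laid out left to right with random intergenic gaps; a
    :class:`SizingError` is raised when they do not fit.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    sequences: Dict[str, str] = {}
    models: List[GeneModel] = []
    genes_per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    gene_counter = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.integers(0, 4, size=config.chrom_length)
        cursor = int(rng.integers(*_incl(config.intergenic_gap_range))) + 1
        for _ in range(genes_per_chrom[ci]):
            gene_counter += 1
            model, span, cds_sense = _draw_gene_structure(
                rng, config, chrom, cursor, gene_counter
            )
            if cursor + span - 1 > config.chrom_length:
                raise SizingError(
                    f"chrom_length={config.chrom_length} too small to place "
                    f"{config.n_genes} genes on {config.n_chroms} chromosomes"
                )
            _imprint_cds(seq, model, cds_sense)
            models.append(model)
            cursor += span + int(rng.integers(*_incl(config.intergenic_gap_range)))
        sequences[chrom] = "".join(BASES[i] for i in seq)
    return sequences, models


def _incl(rng_pair: Tuple[int, int]) -> Tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _draw_gene_structure(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    chrom: str,
    start: int,
    idx: int,
) -> Tuple[GeneModel, int, Optional[str]]:
    n_exons = int(rng.integers(*_incl(cfg.exons_per_gene)))
    exon_lens = [int(rng.integers(*_incl(cfg.exon_length_range))) for _ in range(n_exons)]
    intron_lens = [
        int(rng.integers(*_incl(cfg.intron_length_range))) for _ in range(n_exons - 1)
    ]
    strand = "+" if rng.random() < 0.5 else "-"
    coding = rng.random() >= cfg.ncrna_fraction

    exons: List[Tuple[int, int]] = []
    p = start
    for i, el in enumerate(exon_lens):
        exons.append((p, p + el - 1))
        p += el
        if i < n_exons - 1:
            p += intron_lens[i]
    span = p - start

    gene_id = f"gene{idx:03d}"
    tx_id = f"tx{idx:03d}"
    if not coding:
        model = GeneModel(
            gene_id=gene_id,
            transcript_id=tx_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            biotype="ncRNA",
        )
        return model, span, None

    total = sum(exon_lens)
    u5 = int(rng.integers(*_incl(cfg.utr5_length_range)))
    u3 = int(rng.integers(*_incl(cfg.utr3_length_range)))
    u5 = min(u5, max(1, total - 9))
    u3 = min(u3, max(1, total - u5 - 9))
    cds_len = total - u5 - u3
    u3 += cds_len % 3  # keep CDS divisible by 3
    cds_len -= cds_len % 3
    if cds_len < 9:
        raise SizingError("exons too short to host a coding sequence")

    sense_pos = _sense_positions(exons, strand)
    utr5_iv = _runs(sense_pos[:u5])
    cds_iv = _runs(sense_pos[u5 : u5 + cds_len])
    utr3_iv = _runs(sense_pos[u5 + cds_len :])
    n_codons = cds_len // 3
    middle = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    cds_sense = (
        "ATG"
        + "".join(_SENSE_CODONS[i] for i in middle)
        + _STOP_CODONS[int(rng.integers(0, 3))]
    )
    model = GeneModel(
        gene_id=gene_id,
        transcript_id=tx_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds_iv,
        utr5=utr5_iv,
        utr3=utr3_iv,
        biotype="protein_coding",
    )
    return model, span, cds_sense


def _sense_positions(exons: Sequence[Tuple[int, int]], strand: str) -> List[int]:
    pos = [p for s, e in exons for p in range(s, e + 1)]
    return pos if strand == "+" else pos[::-1]


def _runs(positions: Sequence[int]) -> List[Tuple[int, int]]:
    """Contiguous (start, end) runs of a set of positions."""
    if not positions:
        return []
    ordered = sorted(positions)
    out = []
    run_start = prev = ordered[0]
    for p in ordered[1:]:
        if p != prev + 1:
            out.append((run_start, prev))
            run_start = p
        prev = p
    out.append((run_start, prev))
    return out


def _imprint_cds(seq: np.ndarray, model: GeneModel, cds_sense: Optional[str]) -> None:
    if cds_sense is None:
        return
    sense_pos = _sense_positions(model.cds, model.strand)
    for base, p in zip(cds_sense, sense_pos):
        genomic = base if model.strand == "+" else COMPLEMENT[base]
        seq[p - 1] = _BASE_IDX[genomic]


# ---------------------------------------------------------------------------
# Truth sites and heterozygous DNA SNVs
# ---------------------------------------------------------------------------


def place_truth_sites(
    config: SimulationConfig,
    models: Sequence[GeneModel],
    reference: Dict[str, str],
    exclude: Optional[Set[Tuple[str, int]]] = None,
) -> List[TruthSite]:
    """Draw ground-truth editing sites in exons/introns/UTRs/intergenic space.

    Regions are drawn per ``config.region_weights``, substitution types per
    ``config.edit_type_weights`` (in the transcript sense alphabet), and the
    per-site edit ratio uniformly from ``config.edit_ratio_range``. Raises
    :class:`SizingError` when a region/type bucket runs out of eligible
    positions.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    exclude = exclude or set()
    pools = _position_pools(config, models, reference)
    # bucket eligible positions by (region, sense base); shuffle once
    buckets: Dict[Tuple[str, str], List[Tuple[str, int, Optional[GeneModel]]]] = {}
    for region, entries in pools.items():
        for chrom, pos, model in entries:
            if (chrom, pos) in exclude:
                continue
            base = reference[chrom][pos - 1]
            if model is not None and model.strand == "-":
                base = COMPLEMENT[base]
            buckets.setdefault((region, base), []).append((chrom, pos, model))
    for key in sorted(buckets):
        order = rng.permutation(len(buckets[key]))
        buckets[key] = [buckets[key][i] for i in order]

    regions = sorted(config.region_weights)
    rweights = np.array([config.region_weights[r] for r in regions], dtype=float)
    rweights = rweights / rweights.sum()
    types = sorted(config.edit_type_weights)
    tweights = np.array([config.edit_type_weights[t] for t in types], dtype=float)
    tweights = tweights / tweights.sum()

    lo, hi = config.edit_ratio_range
    sites: List[TruthSite] = []
    for _ in range(config.n_edit_sites):
        region = regions[int(rng.choice(len(regions), p=rweights))]
        rdd_type = types[int(rng.choice(len(types), p=tweights))]
        from_base, to_base = rdd_type[0], rdd_type[-1]
        bucket = buckets.get((region, from_base), [])
        if not bucket:
            raise SizingError(
                f"no eligible {region} positions left with sense base "
                f"{from_base} for type {rdd_type}; requested too many sites"
            )
        chrom, pos, model = bucket.pop()
        sites.append(
            TruthSite(
                chrom=chrom,
                pos=pos,
                ref_base=from_base,
                edited_base=to_base,
                strand=model.strand if model is not None else "+",
                transcript_id=model.transcript_id if model is not None else None,
                true_edit_ratio=float(rng.uniform(lo, hi)),
                region_class=region,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def _position_pools(
    config: SimulationConfig,
    models: Sequence[GeneModel],
    reference: Dict[str, str],
) -> Dict[str, List[Tuple[str, int, Optional[GeneModel]]]]:
    pools: Dict[str, List[Tuple[str, int, Optional[GeneModel]]]] = {
        r: [] for r in ("exonic", "intronic", "UTR5", "UTR3", "intergenic")
    }
    covered: Dict[str, Set[int]] = {c: set() for c in reference}
    for m in models:
        covered[m.chrom].update(range(m.start, m.end + 1))
        junctions = m.splice_junction_positions()
        for s, e in m.cds:
            pools["exonic"].extend((m.chrom, p, m) for p in range(s, e + 1))
        for s, e in m.introns():
            for p in range(s, e + 1):
                if all(abs(p - j) > config.splice_buffer_bp for j in junctions):
                    pools["intronic"].append((m.chrom, p, m))
        for s, e in m.utr5:
            pools["UTR5"].extend((m.chrom, p, m) for p in range(s, e + 1))
        for s, e in m.utr3:
            pools["UTR3"].extend((m.chrom, p, m) for p in range(s, e + 1))
        if not m.is_coding:
            # ncRNA exons count toward the exonic pool for placement purposes
            for s, e in m.exons:
                pools["exonic"].extend((m.chrom, p, m) for p in range(s, e + 1))
    for chrom, seq in reference.items():
        mask = covered[chrom]
        pools["intergenic"].extend(
            (chrom, p, None) for p in range(1, len(seq) + 1) if p not in mask
        )
    return pools


def place_het_snvs(
    config: SimulationConfig,
    reference: Dict[str, str],
    exclude: Optional[Set[Tuple[str, int]]] = None,
) -> List[HetSNV]:
    """Draw true heterozygous DNA SNV positions at ``het_snv_rate`` per bp."""
    rng = np.random.default_rng([config.seed, 2])
    exclude = exclude or set()
    out: List[HetSNV] = []
    for chrom in sorted(reference):
        seq = reference[chrom]
        hits = np.nonzero(rng.random(len(seq)) < config.het_snv_rate)[0]
        for i in hits:
            pos = int(i) + 1
            if (chrom, pos) in exclude:
                continue
            ref = seq[i]
            others = [b for b in BASES if b != ref]
            alt = others[int(rng.integers(0, 3))]
            out.append(HetSNV(chrom=chrom, pos=pos, ref_base=ref, alt_base=alt))
    return out


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------


def simulate_pileups(
    reference: Dict[str, str],
    models: Sequence[GeneModel],
    truth_sites: Sequence[TruthSite],
    het_snvs: Sequence[HetSNV],
    config: SimulationConfig,
    sample_kind: str,
    sample_id: str,
    stream: int = 0,
) -> List[PileupSite]:
    """Simulate per-strand allele counts for one DNA sample or RNA replicate.

    ``sample_kind`` is ``"DNA"`` or ``"RNA"``; ``stream`` separates the random
    streams of different replicates of the same config.
    """
    if sample_kind not in ("DNA", "RNA"):
        raise ValueError("sample_kind must be 'DNA' or 'RNA'")
    config.validate()
    rng = np.random.default_rng([config.seed, 3, stream])
    depth_mean = config.dna_depth_mean if sample_kind == "DNA" else config.rna_depth_mean
    het_at = {(h.chrom, h.pos): h for h in het_snvs}
    truth_at = {(t.chrom, t.pos): t for t in truth_sites} if sample_kind == "RNA" else {}

    sites: List[PileupSite] = []
    for chrom in sorted(reference):
        seq = reference[chrom]
        positions = _covered_positions(
            chrom, len(seq), models, truth_sites, config, sample_kind, rng
        )
        if positions.size == 0:
            continue
        ref_idx = np.fromiter(
            (_BASE_IDX[seq[p - 1]] for p in positions), dtype=np.int64, count=len(positions)
        )
        n = len(positions)
        depth = rng.poisson(depth_mean, size=n)
        counts = np.zeros((n, 4), dtype=np.int64)
        counts[np.arange(n), ref_idx] = depth
        # diploid het SNVs (both DNA and RNA show ~50/50)
        for i, p in enumerate(positions):
            h = het_at.get((chrom, int(p)))
            if h is not None and depth[i] > 0:
                alt_n = rng.binomial(depth[i], 0.5)
                counts[i, _BASE_IDX[h.alt_base]] += alt_n
                counts[i, ref_idx[i]] -= alt_n
        # RNA editing events: edited reads ~ Binomial(depth, edit ratio)
        for i, p in enumerate(positions):
            t = truth_at.get((chrom, int(p)))
            if t is not None and depth[i] > 0:
                edited = rng.binomial(depth[i], t.true_edit_ratio)
                counts[i, _BASE_IDX[t.genomic_alt]] += edited
                counts[i, ref_idx[i]] -= edited
        # uniform substitution error: each read flips to one of the other 3
        if config.error_rate > 0:
            for b in range(4):
                err = rng.binomial(counts[:, b], config.error_rate)
                if err.sum() == 0:
                    continue
                counts[:, b] -= err
                spread = rng.multinomial(err, [1 / 3] * 3)
                other = [o for o in range(4) if o != b]
                for j, o in enumerate(other):
                    counts[:, o] += spread[:, j]
        fwd = rng.binomial(counts, 0.5)
        rev = counts - fwd
        for i, p in enumerate(positions):
            if depth[i] == 0:
                continue
            sites.append(
                PileupSite(
                    sample_id=sample_id,
                    chrom=chrom,
                    pos=int(p),
                    ref_base=BASES[ref_idx[i]],
                    depth=int(depth[i]),
                    counts={
                        base: (int(fwd[i, bi]), int(rev[i, bi]))
                        for bi, base in enumerate(BASES)
                    },
                    mean_baseq=config.mean_baseq,
                    frac_mapq_ge=1.0,
                )
            )
    return sites


def _covered_positions(
    chrom: str,
    length: int,
    models: Sequence[GeneModel],
    truth_sites: Sequence[TruthSite],
    config: SimulationConfig,
    sample_kind: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if sample_kind == "DNA":
        return np.arange(1, length + 1)
    mask = np.zeros(length + 1, dtype=bool)
    for m in models:
        if m.chrom == chrom:
            mask[m.start : m.end + 1] = True
    transcribed = mask.copy()
    if config.intergenic_rna_fraction > 0:
        background = rng.random(length + 1) < config.intergenic_rna_fraction
        mask |= background & ~transcribed
    for t in truth_sites:
        if t.chrom == chrom and t.transcript_id is None:
            lo = max(1, t.pos - _INTERGENIC_TRUTH_WINDOW)
            hi = min(length, t.pos + _INTERGENIC_TRUTH_WINDOW)
            mask[lo : hi + 1] = True
    mask[0] = False
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """In-memory objects and on-disk paths of one simulated tissue."""

    config: SimulationConfig
    reference: Dict[str, str]
    models: List[GeneModel]
    truth_sites: List[TruthSite]
    het_snvs: List[HetSNV]
    dna: List[PileupSite]
    rna_replicates: List[List[PileupSite]]
    paths: Dict[str, object]


def simulate_dataset(
    config: SimulationConfig, outdir: Optional[str] = None, tissue: str = "tissue1"
) -> SimulatedDataset:
    """Run the generator end to end; optionally write all files to ``outdir``.

    Emits reference FASTA, gene GFF3, truth BED (0-based half-open,
    name=sense type, score=round(1000×edit ratio)), one DNA pileup TSV and
    ``config.n_replicates`` RNA pileup TSVs.
    """
    reference, models = generate_reference(config)
    het_snvs = place_het_snvs(config, reference)
    het_positions = {(h.chrom, h.pos) for h in het_snvs}
    truth_sites = place_truth_sites(config, models, reference, exclude=het_positions)
    dna = simulate_pileups(
        reference, models, truth_sites, het_snvs, config, "DNA", f"{tissue}_dna", 0
    )
    rna = [
        simulate_pileups(
            reference,
            models,
            truth_sites,
            het_snvs,
            config,
            "RNA",
            f"{tissue}_rna_rep{r + 1}",
            r + 1,
        )
        for r in range(config.n_replicates)
    ]
    paths: Dict[str, object] = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        paths["reference"] = os.path.join(outdir, "reference.fa")
        write_fasta(reference, paths["reference"])
        paths["annotation"] = os.path.join(outdir, "genes.gff3")
        write_gff3(models, paths["annotation"])
        paths["truth"] = os.path.join(outdir, "truth.bed")
        write_bed(
            [
                BedRecord(
                    chrom=t.chrom,
                    start=t.pos,
                    end=t.pos,
                    name=f"{t.ref_base}-to-{t.edited_base}",
                    score=round(1000 * t.true_edit_ratio),
                )
                for t in truth_sites
            ],
            paths["truth"],
        )
        paths["dna_pileup"] = os.path.join(outdir, f"{tissue}_dna.pileup.tsv")
        write_pileup_table(dna, paths["dna_pileup"])
        rna_paths = []
        for r, sites in enumerate(rna):
            p = os.path.join(outdir, f"{tissue}_rna_rep{r + 1}.pileup.tsv")
            write_pileup_table(sites, p)
            rna_paths.append(p)
        paths["rna_pileups"] = rna_paths
    return SimulatedDataset(
        config=config,
        reference=reference,
        models=models,
        truth_sites=truth_sites,
        het_snvs=het_snvs,
        dna=dna,
        rna_replicates=rna,
        paths=paths,
    )
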