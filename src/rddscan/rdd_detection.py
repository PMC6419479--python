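"""The RDD filter cascade: matched DNA/RNA pileups -> candidate editing sites.

A position is an RNA-DNA difference (RDD) candidate when the DNA sample is
confidently homozygous reference while the RNA sample supports a different
allele. Every common position with at least one non-reference RNA read is
evaluated against the full cascade; failures are recorded per filter (no
short-circuiting), so per-filter attrition can be tabulated. A candidate with
an empty failure list is a PASS site.

Filter codes, in evaluation order:

``min_dna_reads``, ``dna_not_homozygous``, ``rna_not_variant``,
``multiallelic``, ``min_rna_reads``, ``min_alt_reads``, ``min_mapq``,
``min_site_qual``, ``min_baseq``, ``max_fs``, ``splice_window``,
``edit_ratio``, ``repeat``.

The edit-ratio band is inclusive (``[0.10, 0.95]`` by default: the published
rule discards strictly below 10% or strictly above 95%). RNA heterozygosity
is required as variant evidence from the genotype caller (any non-hom-ref
call); discriminating het from hom-alt is left to the edit-ratio band, since
a maximum-likelihood caller labels observed ratios above ~0.9 homozygous-alt,
which would discard genuine high-ratio edits the band deliberately retains.
The splice filter applies only to intronic positions (union over overlapping
transcripts); junctions come from the supplied gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .config import FilterConfig
from .genotyping import call_genotype, is_strictly_homozygous
from .io_formats import BASES, GeneIndex, PileupSite, RepeatMask

FILTER_CODES = (
    "min_dna_reads",
    "dna_not_homozygous",
    "rna_not_variant",
    "multiallelic",
    "min_rna_reads",
    "min_alt_reads",
    "min_mapq",
    "min_site_qual",
    "min_baseq",
    "max_fs",
    "splice_window",
    "edit_ratio",
    "repeat",
)


@dataclass
class RDDCandidate:
    """A DNA-homozygous / RNA-variant position with per-filter diagnostics."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    rna_alt_reads: int
    rna_total_reads: int
    edit_ratio: float
    dna_depth: int
    fs: float
    site_qual: float
    filters_failed: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.filters_failed

    def key(self) -> Tuple[str, int, str, str]:
        """Identity of an editing site: position plus both alleles."""
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass
class DetectionResult:
    """Candidates plus the denominator needed for specificity statements."""

    candidates: List[RDDCandidate]
    n_positions_evaluated: int

    @property
    def passing(self) -> List[RDDCandidate]:
        return [c for c in self.candidates if c.passed]

    def __iter__(self) -> Iterator[RDDCandidate]:
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


def edit_ratio(alt_reads: int, total_reads: int) -> float:
    """Fraction of RNA reads carrying the edited allele."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("alt_reads must lie in [0, total_reads]")
    return alt_reads / total_reads


def splice_proximity(pos: int, gene_index: GeneIndex, chrom: str) -> float:
    """Distance in bp from ``pos`` to the nearest splice junction among
    transcripts overlapping it; ``inf`` if no transcript overlaps. Junctions
    are the first and last base of every intron."""
    return gene_index.splice_proximity(chrom, pos)


def detect_rdds(
    dna: Iterable[PileupSite],
    rna: Iterable[PileupSite],
    config: Optional[FilterConfig] = None,
    gene_index: Optional[GeneIndex] = None,
    repeats: Optional[RepeatMask] = None,
) -> DetectionResult:
    """Run the filter cascade over one DNA sample and one RNA replicate.

    Both streams must be sorted by (chrom, pos) in the same chromosome order;
    positions covered by both are merged. A position yields a candidate when
    the RNA pileup has at least one non-reference read; every filter is then
    evaluated and every failure recorded.
    """
    if config is None:
        config = FilterConfig()
    config.validate()
    exclude_repeats = config.exclude_repeats and repeats is not None

    candidates: List[RDDCandidate] = []
    n_common = 0
    for dna_site, rna_site in _merge_join(dna, rna):
        n_common += 1
        if dna_site.ref_base != rna_site.ref_base:
            raise ValueError(
                f"conflicting reference bases at {dna_site.chrom}:{dna_site.pos}: "
                f"DNA says {dna_site.ref_base}, RNA says {rna_site.ref_base}"
            )
        if rna_site.nonref_count() == 0:
            continue
        cand = _evaluate(dna_site, rna_site, config, gene_index,
                         repeats if exclude_repeats else None)
        candidates.append(cand)
    return DetectionResult(candidates=candidates, n_positions_evaluated=n_common)


def _evaluate(
    dna_site: PileupSite,
    rna_site: PileupSite,
    cfg: FilterConfig,
    gene_index: Optional[GeneIndex],
    repeats: Optional[RepeatMask],
) -> RDDCandidate:
    eps = cfg.genotyping_error_rate
    dna_call = call_genotype(dna_site, eps, cfg.min_alt_reads)
    rna_call = call_genotype(rna_site, eps, cfg.min_alt_reads)
    alt = rna_call.alt_base
    assert alt is not None
    rna_total = rna_site.depth
    rna_alt = rna_site.count(alt)
    ratio = edit_ratio(rna_alt, rna_total)

    failed: List[str] = []
    if dna_site.depth < cfg.min_dna_reads:
        failed.append("min_dna_reads")
    if not is_strictly_homozygous(dna_site, dna_call, cfg.max_dna_alt_reads):
        failed.append("dna_not_homozygous")
    if rna_call.is_hom_ref:
        failed.append("rna_not_variant")
    if not rna_call.is_biallelic:
        failed.append("multiallelic")
    if rna_total < cfg.min_rna_reads:
        failed.append("min_rna_reads")
    if rna_alt < cfg.min_alt_reads:
        failed.append("min_alt_reads")
    if rna_site.frac_mapq_ge < 1.0 or dna_site.frac_mapq_ge < 1.0:
        failed.append("min_mapq")
    if rna_call.site_qual < cfg.min_site_qual:
        failed.append("min_site_qual")
    if rna_site.mean_baseq < cfg.min_mean_baseq:
        failed.append("min_baseq")
    if rna_call.fs > cfg.max_fs:
        failed.append("max_fs")
    if gene_index is not None and gene_index.is_intronic(rna_site.chrom, rna_site.pos):
        if gene_index.splice_proximity(rna_site.chrom, rna_site.pos) <= cfg.splice_window_bp:
            failed.append("splice_window")
    if not (cfg.edit_ratio_min <= ratio <= cfg.edit_ratio_max):
        failed.append("edit_ratio")
    if repeats is not None and (rna_site.chrom, rna_site.pos) in repeats:
        failed.append("repeat")

    return RDDCandidate(
        chrom=rna_site.chrom,
        pos=rna_site.pos,
        ref_base=rna_site.ref_base,
        alt_base=alt,
        rna_alt_reads=rna_alt,
        rna_total_reads=rna_total,
        edit_ratio=ratio,
        dna_depth=dna_site.depth,
        fs=rna_call.fs,
        site_qual=rna_call.site_qual,
        filters_failed=failed,
    )


def _merge_join(
    dna: Iterable[PileupSite], rna: Iterable[PileupSite]
) -> Iterator[Tuple[PileupSite, PileupSite]]:
    """Merge two (chrom, pos)-sorted streams, yielding common positions.

    Chromosome order is taken from order of first appearance; both streams are
    checked for sortedness as they are consumed.
    """
    dna_it = _check_sorted(dna, "DNA")
    rna_it = _check_sorted(rna, "RNA")
    chrom_rank: Dict[str, int] = {}

    def rank(chrom: str) -> int:
        if chrom not in chrom_rank:
            chrom_rank[chrom] = len(chrom_rank)
        return chrom_rank[chrom]

    d = next(dna_it, None)
    r = next(rna_it, None)
    while d is not None and r is not None:
        dk = (rank(d.chrom), d.pos)
        rk = (rank(r.chrom), r.pos)
        if dk == rk:
            yield d, r
            d = next(dna_it, None)
            r = next(rna_it, None)
        elif dk < rk:
            d = next(dna_it, None)
        else:
            r = next(rna_it, None)


def _check_sorted(sites: Iterable[PileupSite], label: str) -> Iterator[PileupSite]:
    seen: Dict[str, int] = {}
    last_chrom = None
    for s in sites:
        if s.chrom != last_chrom:
            if s.chrom in seen:
                raise ValueError(f"{label} pileup not sorted: chromosome "
                                 f"{s.chrom!r} block repeats")
            seen[s.chrom] = 0
            last_chrom = s.chrom
        if s.pos <= seen[s.chrom]:
            raise ValueError(
                f"{label} pileup not sorted at {s.chrom}:{s.pos}"
            )
        seen[s.chrom] = s.pos
        yield s


# ---------------------------------------------------------------------------
# Candidate table IO (TSV mirroring RDDCandidate fields)
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "rna_alt_reads",
    "rna_total_reads",
    "edit_ratio",
    "dna_depth",
    "fs",
    "site_qual",
    "filters_failed",
)


def write_candidate_table(candidates: Sequence[RDDCandidate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.pos),
                        c.ref_base,
                        c.alt_base,
                        str(c.rna_alt_reads),
                        str(c.rna_total_reads),
                        f"{c.edit_ratio:.6f}",
                        str(c.dna_depth),
                        f"{c.fs:.4f}",
                        f"{c.site_qual:.4f}",
                        ",".join(c.filters_failed) or "PASS",
                    ]
                )
                + "\n"
            )


def read_candidate_table(path: str) -> List[RDDCandidate]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if tuple(header.lstrip("#").rstrip("\n").split("\t")) != _CANDIDATE_COLUMNS:
            raise ValueError(f"{path}: not a candidate table")
        for line in fh:
            p = line.rstrip("\n").split("\t")
            out.append(
                RDDCandidate(
                    chrom=p[0],
                    pos=int(p[1]),
                    ref_base=p[2],
                    alt_base=p[3],
                    rna_alt_reads=int(p[4]),
                    rna_total_reads=int(p[5]),
                    edit_ratio=float(p[6]),
                    dna_depth=int(p[7]),
                    fs=float(p[8]),
                    site_qual=float(p[9]),
                    filters_failed=[] if p[10] == "PASS" else p[10].split(","),
                )
            )
    return out
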