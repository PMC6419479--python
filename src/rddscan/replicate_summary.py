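"""Replicate intersection and summary statistics of common editing sites.

A site counts as a reliable ("common") editing site only when it is detected
in every biological replicate of a tissue, keyed by (chrom, pos, ref, alt):
the same position edited to different bases in different replicates is not
one editing site. Summaries report the region histogram, the 12-way type
spectrum over sites assignable to a single transcript strand, the distinct
annotated genes per tissue, cross-tissue gene overlaps, and the burden of
amino-acid-changing (nonsynonymous or stop-gain) edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .annotation import REGION_CLASSES, AnnotatedRDD
from .config import RDD_TYPES

Key = Tuple[str, int, str, str]


def intersect_replicates(sets: Sequence[Set[Key]]) -> Set[Key]:
    """Exact intersection of per-replicate candidate key sets."""
    if not sets:
        raise ValueError("need at least one replicate set")
    common = set(sets[0])
    for s in sets[1:]:
        common &= s
    return common


@dataclass
class ReplicateSet:
    """PASS candidates of one tissue across replicates, plus their common core."""

    tissue: str
    replicate_ids: List[str]
    per_replicate: Dict[str, Set[Key]]
    common: Set[Key]
    edit_ratios: Dict[Key, Dict[str, float]]

    @classmethod
    def from_candidates(
        cls, tissue: str, per_replicate: Dict[str, Sequence[AnnotatedRDD]]
    ) -> "ReplicateSet":
        keys = {
            rep: {s.key() for s in sites if s.candidate.passed}
            for rep, sites in per_replicate.items()
        }
        rep_ids = list(per_replicate)
        common = intersect_replicates([keys[r] for r in rep_ids])
        ratios: Dict[Key, Dict[str, float]] = {k: {} for k in common}
        for rep, sites in per_replicate.items():
            for s in sites:
                if s.key() in ratios:
                    ratios[s.key()][rep] = s.candidate.edit_ratio
        return cls(
            tissue=tissue,
            replicate_ids=rep_ids,
            per_replicate=keys,
            common=common,
            edit_ratios=ratios,
        )

    def mean_edit_ratio(self, key: Key) -> float:
        return mean(self.edit_ratios[key].values())


def summarize(
    common_by_tissue: Dict[str, Sequence[AnnotatedRDD]] | Sequence[AnnotatedRDD],
) -> dict:
    """Summary report over common annotated sites, per tissue.

    Accepts either ``{tissue: [AnnotatedRDD, ...]}`` or a bare sequence (then
    reported under a single unnamed tissue). For each tissue: the region
    histogram, the 12-type histogram with fractions over strand-assignable
    sites, the distinct gene list (intergenic sites excluded), and counts of
    amino-acid-changing sites/genes. Cross-tissue sections report pairwise
    gene-overlap counts.
    """
    if not isinstance(common_by_tissue, dict):
        common_by_tissue = {"all": list(common_by_tissue)}
    report: dict = {"tissues": {}, "gene_overlap": {}}
    genes_by_tissue: Dict[str, Set[str]] = {}
    for tissue, sites in common_by_tissue.items():
        region_hist = {r: 0 for r in REGION_CLASSES}
        type_hist = {t: 0 for t in RDD_TYPES}
        genes: Set[str] = set()
        aa_sites = 0
        aa_genes: Set[str] = set()
        for s in sites:
            region_hist[s.region] += 1
            if s.rdd_type != "unassigned":
                type_hist[s.rdd_type] += 1
            if s.region != "intergenic":
                genes.update(s.gene_ids)
            if s.consequence in ("nonsynonymous", "stopgain"):
                aa_sites += 1
                aa_genes.update(s.gene_ids)
        n_typed = sum(type_hist.values())
        type_fractions = {
            t: (c / n_typed if n_typed else 0.0) for t, c in type_hist.items()
        }
        genes_by_tissue[tissue] = genes
        report["tissues"][tissue] = {
            "n_sites": len(sites),
            "region_histogram": region_hist,
            "type_histogram": type_hist,
            "type_fractions": type_fractions,
            "n_typed": n_typed,
            "genes": sorted(genes),
            "n_genes": len(genes),
            "aa_changing_sites": aa_sites,
            "aa_changing_genes": sorted(aa_genes),
        }
    tissues = list(common_by_tissue)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1 :]:
            report["gene_overlap"][f"{a}|{b}"] = len(
                genes_by_tissue[a] & genes_by_tissue[b]
            )
    return report
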