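"""Configuration blocks for the simulation and the detection filter cascade.

Three dataclasses mirror the three things a run needs to know: how synthetic
data are generated (:class:`SimulationConfig`), which thresholds the RNA-DNA
difference (RDD) filter cascade applies (:class:`FilterConfig`), and how a
whole pipeline invocation is wired together (:class:`PipelineConfig`).
Pipeline configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

#: The 12 single-nucleotide substitution classes, in transcript sense-strand
#: alphabet ("A-to-G" is the signature of A-to-I editing).
RDD_TYPES: Tuple[str, ...] = tuple(
    f"{a}-to-{b}" for a in "ACGT" for b in "ACGT" if a != b
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _default_type_weights() -> Dict[str, float]:
    # A-to-I dominated spectrum with a C-to-U component, matching what bulk
    # RNA-seq surveys of mammalian tissues report for strand-resolved types.
    weights = {t: 0.05 for t in RDD_TYPES}
    weights["A-to-G"] = 0.40
    weights["C-to-T"] = 0.10
    return weights


def _default_region_weights() -> Dict[str, float]:
    return {
        "exonic": 0.35,
        "intronic": 0.30,
        "UTR5": 0.10,
        "UTR3": 0.10,
        "intergenic": 0.15,
    }


@dataclass
class FilterConfig:
    """Thresholds of the RDD filter cascade.

    Defaults are the published cascade: DNA sites need >=4 reads and complete
    homozygosity; RNA variant sites need >=10 reads, >=2 alternative reads,
    all covering reads at MAPQ >= 20, phred site quality >= 95, Fisher strand
    value <= 30, an edit ratio inside [0.10, 0.95] (bounds inclusive: the rule
    discards strictly "< 10% or > 95%"), and intronic sites farther than 4 bp
    from a splice junction.
    """

    min_dna_reads: int = 4
    min_rna_reads: int = 10
    min_alt_reads: int = 2
    min_mapq: int = 20
    min_site_qual: float = 95.0
    max_fs: float = 30.0
    edit_ratio_min: float = 0.10
    edit_ratio_max: float = 0.95
    splice_window_bp: int = 4
    max_dna_alt_reads: int = 0
    exclude_repeats: bool = True
    #: sanity floor on the mean phred base quality of a site
    min_mean_baseq: float = 20.0
    #: per-read substitution-error probability of the genotype caller
    genotyping_error_rate: float = 0.01

    def validate(self) -> None:
        if not (0.0 < self.edit_ratio_min < self.edit_ratio_max < 1.0):
            raise ValueError(
                "edit ratio bounds must satisfy 0 < min < max < 1, got "
                f"[{self.edit_ratio_min}, {self.edit_ratio_max}]"
            )
        for name in (
            "min_dna_reads",
            "min_rna_reads",
            "min_alt_reads",
            "min_mapq",
            "splice_window_bp",
            "max_dna_alt_reads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.genotyping_error_rate < 0.5):
            raise ValueError("genotyping_error_rate must be in (0, 0.5)")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome / pileup generator.

    The defaults define the reference study conditions: a 2-chromosome toy
    genome, 3 RNA replicates per tissue at mean depth 40x against one DNA
    sample at 25x, platform substitution error 1e-3, 200 injected editing
    sites with edit ratios uniform on [0.15, 0.90], and heterozygous DNA SNVs
    at 1 per kb so the homozygosity rejection path is exercised.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 50_000
    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (2, 4)
    dna_depth_mean: float = 25.0
    rna_depth_mean: float = 40.0
    error_rate: float = 0.001
    het_snv_rate: float = 0.001
    n_edit_sites: int = 200
    edit_ratio_range: Tuple[float, float] = (0.15, 0.90)
    edit_type_weights: Dict[str, float] = field(default_factory=_default_type_weights)
    n_replicates: int = 3
    # --- structural knobs of the toy genome ---
    exon_length_range: Tuple[int, int] = (120, 300)
    intron_length_range: Tuple[int, int] = (80, 400)
    utr5_length_range: Tuple[int, int] = (30, 80)
    utr3_length_range: Tuple[int, int] = (40, 120)
    intergenic_gap_range: Tuple[int, int] = (300, 1500)
    ncrna_fraction: float = 0.2
    #: fraction of intergenic positions that receive RNA background coverage
    intergenic_rna_fraction: float = 0.10
    region_weights: Dict[str, float] = field(default_factory=_default_region_weights)
    mean_baseq: float = 37.0
    #: intronic truth sites are kept at least this far from splice junctions
    splice_buffer_bp: int = 4

    def validate(self) -> None:
        lo, hi = self.edit_ratio_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("edit_ratio_range must lie within (0, 1)")
        total = sum(self.edit_type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"edit_type_weights must sum to 1, got {total}")
        unknown = set(self.edit_type_weights) - set(RDD_TYPES)
        if unknown:
            raise ValueError(f"unknown substitution types: {sorted(unknown)}")
        if self.dna_depth_mean <= 0 or self.rna_depth_mean <= 0:
            raise ValueError("sequencing depths must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("exons_per_gene must be a non-empty [lo, hi] range")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.n_genes < 0 or self.n_edit_sites < 0 or self.n_replicates < 1:
            raise ValueError("counts must be non-negative (>=1 replicate)")
        if not (0.0 <= self.het_snv_rate < 1.0):
            raise ValueError("het_snv_rate must be in [0, 1)")


@dataclass
class PipelineConfig:
    """Wiring of a full pipeline run: input paths per tissue plus both blocks.

    ``rna_pileups`` maps a tissue label to the list of per-replicate pileup
    TSVs; ``dna_pileup`` maps the same label to the single matched DNA pileup.
    When ``simulate`` is requested these paths are produced by the generator.
    """

    output_dir: str = "rddscan_out"
    seed: int = 0
    log_level: str = "INFO"
    reference: Optional[str] = None
    annotation: Optional[str] = None
    repeats: Optional[str] = None
    dna_pileup: Dict[str, str] = field(default_factory=dict)
    rna_pileups: Dict[str, List[str]] = field(default_factory=dict)
    filters: FilterConfig = field(default_factory=FilterConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        self.filters.validate()
        self.simulation.validate()

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML has no tuple type; normalise to lists for a lossless round trip
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        filters = FilterConfig(**d.pop("filters", {}))
        sim = _sim_from_dict(d.pop("simulation", {}))
        return cls(filters=filters, simulation=sim, **d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


_SIM_TUPLE_FIELDS = (
    "exons_per_gene",
    "edit_ratio_range",
    "exon_length_range",
    "intron_length_range",
    "utr5_length_range",
    "utr3_length_range",
    "intergenic_gap_range",
)


def _sim_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in _SIM_TUPLE_FIELDS:
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def _tuples_to_lists(obj):
    if isinstance(obj, tuple):
        return [_tuples_to_lists(x) for x in obj]
    if isinstance(obj, list):
        return [_tuples_to_lists(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    return obj
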