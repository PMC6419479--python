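"""Strand-corrected typing, region classification and coding consequences.

RNA-seq without strand information cannot distinguish an A>G mismatch on a
plus-strand transcript from a T>C mismatch read off a minus-strand one: both
are A-to-I editing on the transcript sense strand. Typing therefore relabels
each genomic (plus-strand) substitution into the sense-strand alphabet of the
transcripts overlapping the site. Sites covered by transcripts on both
strands (bidirectional transcription) or by none cannot be assigned a type
and are excluded from the type spectrum.

Region classes follow the conventional annotation precedence when several
transcripts overlap a position::

    exonic (CDS) > splicing > ncRNA > UTR5 > UTR3 > intronic > intergenic

"splicing" means within a configurable window of a splice junction, on either
side of it. Coding consequences substitute the edited base into the spliced
CDS codon (transcript orientation) and translate both codons with the
standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .config import COMPLEMENT, RDD_TYPES
from .io_formats import GeneIndex, GeneModel
from .rdd_detection import RDDCandidate

REGION_CLASSES = ("exonic", "splicing", "ncRNA", "UTR5", "UTR3", "intronic", "intergenic")

CONSEQUENCES = ("synonymous", "nonsynonymous", "stopgain", "stoploss", "n/a")


@dataclass
class AnnotatedRDD:
    """An RDD candidate plus its transcript-level annotation."""

    candidate: RDDCandidate
    rdd_type: str  # one of the 12 labels, or "unassigned"
    region: str
    gene_ids: List[str] = field(default_factory=list)
    consequence: str = "n/a"
    aa_change: Optional[str] = None
    strands: Set[str] = field(default_factory=set)

    def key(self):
        return self.candidate.key()


def strand_correct_type(ref_base: str, alt_base: str, strands: Set[str]) -> str:
    """Relabel a genomic substitution into the transcript sense alphabet.

    ``strands`` is the set of strands of transcripts overlapping the site:
    {"+"} keeps the substitution, {"-"} complements both bases, and an empty
    or mixed set yields "unassigned" (bidirectional or untranscribed regions
    are not taken into any category).
    """
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    if strands == {"+"}:
        return f"{ref_base}-to-{alt_base}"
    if strands == {"-"}:
        return f"{COMPLEMENT[ref_base]}-to-{COMPLEMENT[alt_base]}"
    return "unassigned"


def classify_region(
    chrom: str,
    pos: int,
    index: GeneIndex,
    splice_window_bp: int = 4,
) -> Tuple[str, List[str]]:
    """Region class of a position plus the genes supporting the winning class.

    Precedence across all overlapping transcripts: exonic (CDS) > splicing
    (within ``splice_window_bp`` of a junction, either side) > ncRNA exon >
    UTR5 > UTR3 > intronic > intergenic.
    """
    support: Dict[str, Set[str]] = {r: set() for r in REGION_CLASSES}
    for m in index.overlapping(chrom, pos):
        classes = _classes_in_model(pos, m, splice_window_bp)
        for cls in classes:
            support[cls].add(m.gene_id)
    for cls in REGION_CLASSES[:-1]:
        if support[cls]:
            return cls, sorted(support[cls])
    return "intergenic", []


def _classes_in_model(pos: int, m: GeneModel, window: int) -> Set[str]:
    out: Set[str] = set()
    near_junction = any(abs(pos - j) <= window for j in m.splice_junction_positions())
    in_exon = _in(m.exons, pos)
    if in_exon:
        if _in(m.cds, pos):
            out.add("exonic")
        elif not m.is_coding:
            out.add("ncRNA")
        elif _in(m.utr5, pos):
            out.add("UTR5")
        elif _in(m.utr3, pos):
            out.add("UTR3")
        else:
            # coding exon base without CDS/UTR sub-annotation: call it exonic
            out.add("exonic")
    else:
        out.add("intronic")
    if near_junction and "exonic" not in out:
        out.add("splicing")
    return out


def _in(intervals: Sequence[Tuple[int, int]], pos: int) -> bool:
    return any(s <= pos <= e for s, e in intervals)


# ---------------------------------------------------------------------------
# Coding consequences
# ---------------------------------------------------------------------------


def coding_consequence(
    pos: int,
    ref_base: str,
    alt_base: str,
    model: GeneModel,
    chrom_seq: str,
) -> Tuple[str, Optional[str]]:
    """Consequence of substituting ``alt_base`` at CDS position ``pos``.

    ``ref_base``/``alt_base`` are genomic plus-strand bases; ``chrom_seq`` is
    the full chromosome sequence. The affected codon is built from the spliced
    CDS in transcript orientation, the edited base substituted at its codon
    offset, and both codons translated with the standard genetic code.
    Returns (consequence, aa_change) with aa_change like ``"Y→C"`` (None when
    synonymous). Raises ValueError when ``pos`` is not inside the model's CDS.
    """
    if not model.is_coding:
        raise ValueError(f"{model.transcript_id} has no CDS")
    # genomic positions of the spliced CDS, transcript (sense) order
    positions: List[int] = []
    for s, e in model.cds:
        positions.extend(range(s, e + 1))
    if model.strand == "-":
        positions.reverse()
    try:
        cds_index = positions.index(pos)
    except ValueError:
        raise ValueError(
            f"position {pos} is not in the CDS of {model.transcript_id}"
        ) from None
    if len(positions) % 3 != 0:
        raise ValueError(f"{model.transcript_id}: CDS length not divisible by 3")

    def sense(p: int) -> str:
        b = chrom_seq[p - 1].upper()
        return b if model.strand == "+" else COMPLEMENT[b]

    codon_start = cds_index - (cds_index % 3)
    codon_positions = positions[codon_start : codon_start + 3]
    ref_codon = "".join(sense(p) for p in codon_positions)
    sense_ref = ref_base if model.strand == "+" else COMPLEMENT[ref_base]
    sense_alt = alt_base if model.strand == "+" else COMPLEMENT[alt_base]
    offset = cds_index % 3
    if ref_codon[offset] != sense_ref:
        raise ValueError(
            f"reference mismatch at {model.transcript_id} CDS position "
            f"{cds_index}: codon has {ref_codon[offset]}, caller says {sense_ref}"
        )
    alt_codon = ref_codon[:offset] + sense_alt + ref_codon[offset + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous", None
    if aa_alt == "*":
        consequence = "stopgain"
    elif aa_ref == "*":
        consequence = "stoploss"
    else:
        consequence = "nonsynonymous"
    return consequence, f"{aa_ref}→{aa_alt}"


# ---------------------------------------------------------------------------
# Candidate annotation
# ---------------------------------------------------------------------------


def annotate_candidates(
    candidates: Sequence[RDDCandidate],
    index: GeneIndex,
    reference: Dict[str, str],
    splice_window_bp: int = 4,
) -> List[AnnotatedRDD]:
    """Attach type, region and coding consequence to each candidate."""
    out = []
    for c in candidates:
        strands = index.transcript_strands(c.chrom, c.pos)
        rdd_type = strand_correct_type(c.ref_base, c.alt_base, strands)
        region, gene_ids = classify_region(c.chrom, c.pos, index, splice_window_bp)
        consequence, aa_change = "n/a", None
        if region == "exonic":
            for m in index.overlapping(c.chrom, c.pos):
                if m.is_coding and _in(m.cds, c.pos):
                    consequence, aa_change = coding_consequence(
                        c.pos, c.ref_base, c.alt_base, m, reference[c.chrom]
                    )
                    break
        out.append(
            AnnotatedRDD(
                candidate=c,
                rdd_type=rdd_type,
                region=region,
                gene_ids=gene_ids,
                consequence=consequence,
                aa_change=aa_change,
                strands=strands,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Annotated table IO
# ---------------------------------------------------------------------------

_ANNOTATED_COLUMNS = (
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
    "rdd_type",
    "region",
    "gene_ids",
    "consequence",
    "aa_change",
    "strands",
)


def write_annotated_table(sites: Sequence[AnnotatedRDD], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_ANNOTATED_COLUMNS) + "\n")
        for s in sites:
            c = s.candidate
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
                        s.rdd_type,
                        s.region,
                        ",".join(s.gene_ids) or ".",
                        s.consequence,
                        s.aa_change or ".",
                        "".join(sorted(s.strands)) or ".",
                    ]
                )
                + "\n"
            )


def read_annotated_table(path: str) -> List[AnnotatedRDD]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if tuple(header.lstrip("#").rstrip("\n").split("\t")) != _ANNOTATED_COLUMNS:
            raise ValueError(f"{path}: not an annotated RDD table")
        for line in fh:
            p = line.rstrip("\n").split("\t")
            cand = RDDCandidate(
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
            out.append(
                AnnotatedRDD(
                    candidate=cand,
                    rdd_type=p[11],
                    region=p[12],
                    gene_ids=[] if p[13] == "." else p[13].split(","),
                    consequence=p[14],
                    aa_change=None if p[15] == "." else p[15],
                    strands=set() if p[16] == "." else set(p[16]),
                )
            )
    return out
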