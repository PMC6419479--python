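"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* pileup TSV — per-site, per-strand allele counts; the pipeline's atomic
  input. Columns (tab-separated, ``#``-prefixed header)::

      sample_id chrom pos ref depth A_fwd A_rev C_fwd C_rev G_fwd G_rev
      T_fwd T_rev mean_baseq frac_mapq_ge

  ``pos`` is 1-based. ``depth`` must equal the sum of the eight strand
  counts. Rows must be sorted by (chrom, pos); chromosome blocks must not
  repeat.
* gene models — GFF3 with gene/mRNA/exon and optional CDS / five_prime_UTR /
  three_prime_UTR children (parsed through :mod:`gffutils`); an mRNA with no
  CDS is treated as non-coding.
* reference — FASTA via Biopython.
* repeats / truth regions — BED (0-based half-open on disk, converted to
  1-based inclusive in memory).
* results — a minimal single-sample VCF 4.2 writer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

BASES = ("A", "C", "G", "T")
STRANDS = ("+", "-")

PILEUP_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "depth",
    "A_fwd",
    "A_rev",
    "C_fwd",
    "C_rev",
    "G_fwd",
    "G_rev",
    "T_fwd",
    "T_rev",
    "mean_baseq",
    "frac_mapq_ge",
)


class PileupFormatError(ValueError):
    """Raised for malformed or unsorted pileup tables (names the line)."""


class GFF3FormatError(ValueError):
    """Raised for gene-model files the pipeline cannot interpret."""


# ---------------------------------------------------------------------------
# PileupSite
# ---------------------------------------------------------------------------


@dataclass
class PileupSite:
    """Per-position, per-strand allele counts for one sample.

    ``counts`` maps each base to its (forward, reverse) read counts after the
    upstream MAPQ filter; ``frac_mapq_ge`` records which fraction of covering
    reads met that MAPQ threshold, so the mapping-quality rule can also be
    asserted site-level.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    counts: Dict[str, Tuple[int, int]]
    mean_baseq: float
    frac_mapq_ge: float

    def validate(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        total = 0
        for base in BASES:
            fwd, rev = self.counts[base]
            if fwd < 0 or rev < 0:
                raise ValueError("allele counts must be >= 0")
            total += fwd + rev
        if total != self.depth:
            raise ValueError(
                f"depth {self.depth} != sum of allele counts {total} at "
                f"{self.chrom}:{self.pos}"
            )

    def count(self, base: str) -> int:
        fwd, rev = self.counts[base]
        return fwd + rev

    def strand_counts(self, base: str) -> Tuple[int, int]:
        return self.counts[base]

    def nonref_count(self) -> int:
        return self.depth - self.count(self.ref_base)

    def nonref_bases(self) -> List[Tuple[str, int]]:
        """Non-reference bases with at least one read, highest count first
        (ties broken alphabetically, so results are deterministic)."""
        out = [(b, self.count(b)) for b in BASES if b != self.ref_base and self.count(b) > 0]
        out.sort(key=lambda bc: (-bc[1], bc[0]))
        return out


def write_pileup_table(sites: Iterable[PileupSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        for s in sites:
            row = [s.sample_id, s.chrom, str(s.pos), s.ref_base, str(s.depth)]
            for base in BASES:
                fwd, rev = s.counts[base]
                row.append(str(fwd))
                row.append(str(rev))
            row.append(f"{s.mean_baseq:.2f}")
            row.append(f"{s.frac_mapq_ge:.4f}")
            fh.write("\t".join(row) + "\n")


def read_pileup_table(path: str) -> Iterator[PileupSite]:
    """Stream validated :class:`PileupSite` rows from a pileup TSV.

    Raises :class:`PileupFormatError` naming the offending line for malformed
    rows, invariant violations, or (chrom, pos) sort-order violations.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise PileupFormatError(f"{path}: line 1: missing '#'-prefixed header")
        cols = tuple(header[1:].rstrip("\n").split("\t"))
        if cols != PILEUP_COLUMNS:
            raise PileupFormatError(
                f"{path}: line 1: header does not match pileup schema"
            )
        seen_chroms: List[str] = []
        last_pos = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(PILEUP_COLUMNS):
                raise PileupFormatError(
                    f"{path}: line {lineno}: expected {len(PILEUP_COLUMNS)} "
                    f"columns, got {len(parts)}"
                )
            try:
                site = PileupSite(
                    sample_id=parts[0],
                    chrom=parts[1],
                    pos=int(parts[2]),
                    ref_base=parts[3],
                    depth=int(parts[4]),
                    counts={
                        base: (int(parts[5 + 2 * i]), int(parts[6 + 2 * i]))
                        for i, base in enumerate(BASES)
                    },
                    mean_baseq=float(parts[13]),
                    frac_mapq_ge=float(parts[14]),
                )
                site.validate()
            except ValueError as exc:
                raise PileupFormatError(f"{path}: line {lineno}: {exc}") from exc
            if not seen_chroms or site.chrom != seen_chroms[-1]:
                if site.chrom in seen_chroms:
                    raise PileupFormatError(
                        f"{path}: line {lineno}: chromosome block "
                        f"{site.chrom!r} repeats; input must be sorted"
                    )
                seen_chroms.append(site.chrom)
                last_pos = 0
            if site.pos <= last_pos:
                raise PileupFormatError(
                    f"{path}: line {lineno}: positions not strictly increasing "
                    f"within {site.chrom!r}"
                )
            last_pos = site.pos
            yield site


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One transcript: strand, exons and optional CDS/UTR structure.

    All intervals are 1-based inclusive ``(start, end)`` tuples in genomic
    order. ``cds`` is empty for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt[0] <= prev[1]:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def introns(self) -> List[Tuple[int, int]]:
        return [
            (prev[1] + 1, nxt[0] - 1)
            for prev, nxt in zip(self.exons, self.exons[1:])
            if nxt[0] - prev[1] > 1
        ]

    def splice_junction_positions(self) -> List[int]:
        """First and last base of every intron (1-based)."""
        out: List[int] = []
        for s, e in self.introns():
            out.append(s)
            if e != s:
                out.append(e)
        return out

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


def _covers(intervals: Sequence[Tuple[int, int]], pos: int) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    """Emit gene/mRNA/exon(/CDS/UTR) features, one gene per transcript."""
    by_gene: Dict[str, List[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            g_start = min(t.start for t in txs)
            g_end = max(t.end for t in txs)
            first = txs[0]
            fh.write(
                f"{first.chrom}\trddscan\tgene\t{g_start}\t{g_end}\t.\t"
                f"{first.strand}\t.\tID={gene_id}\n"
            )
            for t in txs:
                fh.write(
                    f"{t.chrom}\trddscan\tmRNA\t{t.start}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene_id};"
                    f"biotype={t.biotype}\n"
                )
                for kind, ivs in (
                    ("exon", t.exons),
                    ("CDS", t.cds),
                    ("five_prime_UTR", t.utr5),
                    ("three_prime_UTR", t.utr3),
                ):
                    for i, (s, e) in enumerate(ivs, start=1):
                        phase = "."
                        fh.write(
                            f"{t.chrom}\trddscan\t{kind}\t{s}\t{e}\t.\t"
                            f"{t.strand}\t{phase}\t"
                            f"ID={t.transcript_id}.{kind}.{i};"
                            f"Parent={t.transcript_id}\n"
                        )


def read_gff3(path: str) -> List[GeneModel]:
    """Parse gene models: one :class:`GeneModel` per mRNA feature.

    Children are grouped by their ``Parent`` attribute. An mRNA without CDS
    children is labelled ``ncRNA``. Raises :class:`GFF3FormatError` for
    mRNAs with unknown strand or child features with unresolvable parents.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    mrnas = {f.id: f for f in db.features_of_type("mRNA")}
    children: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
        mid: {"exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []}
        for mid in mrnas
    }
    for kind in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
        for feat in db.features_of_type(kind):
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise GFF3FormatError(f"{kind} feature {feat.id} has no Parent")
            for parent in parents:
                if parent not in mrnas:
                    raise GFF3FormatError(
                        f"{kind} feature {feat.id}: parent {parent!r} is not a "
                        "known mRNA"
                    )
                children[parent][kind].append((feat.start, feat.end))
    models = []
    for mid, feat in mrnas.items():
        if feat.strand not in STRANDS:
            raise GFF3FormatError(f"mRNA {mid}: strand {feat.strand!r} is not +/-")
        gene_id = feat.attributes.get("Parent", [mid])[0]
        kids = children[mid]
        if not kids["exon"]:
            raise GFF3FormatError(f"mRNA {mid} has no exon children")
        biotype = "protein_coding" if kids["CDS"] else "ncRNA"
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mid,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=kids["exon"],
                cds=kids["CDS"],
                utr5=kids["five_prime_UTR"],
                utr3=kids["three_prime_UTR"],
                biotype=biotype,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


class GeneIndex:
    """Interval index over gene models for position queries.

    Answers, per genomic position: which transcripts overlap, the distance to
    the nearest splice junction among overlapping transcripts, and whether the
    position is intronic/exonic in any of them.
    """

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._trees: Dict[str, IntervalTree] = {}
        for m in self.models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree.addi(m.start, m.end + 1, m)  # half-open internally

    def overlapping(self, chrom: str, pos: int) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda m: m.transcript_id)

    def transcript_strands(self, chrom: str, pos: int) -> set:
        return {m.strand for m in self.overlapping(chrom, pos)}

    def is_intronic(self, chrom: str, pos: int) -> bool:
        return any(_covers(m.introns(), pos) for m in self.overlapping(chrom, pos))

    def splice_proximity(self, chrom: str, pos: int) -> float:
        """Distance in bp to the nearest splice junction of any transcript
        overlapping ``pos`` (0 if ``pos`` is a junction base); ``inf`` when no
        transcript overlaps the position or none has introns."""
        models = self.overlapping(chrom, pos)
        if not models:
            return float("inf")
        best = float("inf")
        for m in models:
            for j in m.splice_junction_positions():
                best = min(best, abs(pos - j))
        return best


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive in memory)
# ---------------------------------------------------------------------------


@dataclass
class BedRecord:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    name: Optional[str] = None
    score: Optional[int] = None


def read_bed(path: str) -> List[BedRecord]:
    """Read BED3+ records, converting [start, end) 0-based to 1-based
    inclusive: a one-length interval [k, k+1) becomes position k+1."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
            start0, end0 = int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"{path}: line {lineno}: empty/negative interval")
            out.append(
                BedRecord(
                    chrom=parts[0],
                    start=start0 + 1,
                    end=end0,
                    name=parts[3] if len(parts) > 3 else None,
                    score=int(parts[4]) if len(parts) > 4 else None,
                )
            )
    return out


def write_bed(records: Sequence[BedRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.chrom, str(r.start - 1), str(r.end)]
            if r.name is not None:
                cols.append(r.name)
                if r.score is not None:
                    cols.append(str(r.score))
            fh.write("\t".join(cols) + "\n")


class RepeatMask:
    """Membership test for repeat regions loaded from a BED file."""

    def __init__(self, records: Iterable[BedRecord] = ()):
        self._trees: Dict[str, IntervalTree] = {}
        for r in records:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1)

    @classmethod
    def from_bed(cls, path: str) -> "RepeatMask":
        return cls(read_bed(path))

    def __contains__(self, key: Tuple[str, int]) -> bool:
        chrom, pos = key
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(pos))


# ---------------------------------------------------------------------------
# VCF writer (minimal, single sample-less VCF 4.2)
# ---------------------------------------------------------------------------

_VCF_FILTER_DESCRIPTIONS = {
    "min_dna_reads": "DNA depth below the minimum genomic read support",
    "dna_not_homozygous": "DNA genotype not strictly homozygous reference",
    "rna_not_variant": "no RNA variant genotype supported at the site",
    "multiallelic": "more than one alternative allele supported",
    "min_rna_reads": "RNA depth below the minimum read support",
    "min_alt_reads": "too few reads supporting the alternative allele",
    "min_mapq": "covering reads below the mapping-quality threshold",
    "min_site_qual": "phred-scaled site variant quality below threshold",
    "min_baseq": "mean base quality below the sanity floor",
    "max_fs": "Fisher strand-bias value above threshold",
    "splice_window": "intronic site within the splice-junction window",
    "edit_ratio": "edit ratio outside the retained band",
    "repeat": "site overlaps a repeat region",
}


def write_rdd_vcf(sites: Sequence, path: str, contigs: Optional[Sequence[str]] = None) -> None:
    """Write annotated RDDs (or bare candidates) as a minimal VCF 4.2.

    FILTER is ``PASS`` or the semicolon-joined failed-filter codes; INFO
    carries the edit ratio, strand-corrected type, region class, amino-acid
    change and transcript strand set where available.
    """
    if contigs is None:
        contigs = sorted({_cand(s).chrom for s in sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rddscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for code, desc in _VCF_FILTER_DESCRIPTIONS.items():
            fh.write(f'##FILTER=<ID={code},Description="{desc}">\n')
        fh.write(
            '##INFO=<ID=EDITRATIO,Number=1,Type=Float,Description="Fraction of'
            ' RNA reads carrying the edited allele">\n'
            '##INFO=<ID=RDDTYPE,Number=1,Type=String,Description="Strand-corrected'
            ' substitution type">\n'
            '##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">\n'
            '##INFO=<ID=GENES,Number=.,Type=String,Description="Supporting genes">\n'
            '##INFO=<ID=AACHANGE,Number=1,Type=String,Description="Amino acid change">\n'
            '##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand(s)">\n'
            '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher'
            ' strand p-value">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda s: (_cand(s).chrom, _cand(s).pos)):
            c = _cand(s)
            filt = "PASS" if not c.filters_failed else ";".join(c.filters_failed)
            info = [f"EDITRATIO={c.edit_ratio:.3f}", f"FS={c.fs:.2f}"]
            rdd_type = getattr(s, "rdd_type", None)
            if rdd_type is not None:
                info.append(f"RDDTYPE={rdd_type}")
                info.append(f"REGION={s.region}")
                if s.gene_ids:
                    info.append("GENES=" + ",".join(s.gene_ids))
                if s.aa_change:
                    info.append("AACHANGE=" + s.aa_change.replace("→", ">"))
                if getattr(s, "strands", None):
                    info.append("STRAND=" + "".join(sorted(s.strands)))
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_base}\t{c.alt_base}\t"
                f"{c.site_qual:.2f}\t{filt}\t{';'.join(info)}\n"
            )


def _cand(site):
    return getattr(site, "candidate", site)
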