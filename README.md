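# rddscan

Detection of **RNA-DNA differences (RDDs)** — the observable signature of RNA
editing — from matched DNA and RNA per-site pileups, for transcriptomics
researchers who want a tested, reusable reimplementation of the standard
RDD filter cascade together with a ground-truth synthetic data generator.

## The problem and the method

RNA editing (chiefly A-to-I deamination by ADAR enzymes, read as A-to-G by
sequencers, and the rarer C-to-U) creates positions where an individual's RNA
reads carry an allele its genomic DNA does not. Calling such sites naively
from RNA-seq is dominated by artifacts, so detection is a cascade of filters
over matched DNA/RNA evidence at each site:

1. **DNA evidence** — at least 4 genomic reads and *complete* homozygosity
   (any alternative DNA read disqualifies the site: it could be an unnoticed
   heterozygous SNV, not editing).
2. **RNA evidence** — a biallelic SNV call with ≥ 10 RNA reads, ≥ 2 reads on
   the alternative allele, all covering reads at mapping quality ≥ 20, mean
   base quality ≥ 20, and phred-scaled site variant quality ≥ 95, where the
   site quality is −10·log₁₀ of the flat-prior posterior of homozygous
   reference under a per-read error model
   (P(alt | ref/ref) = ε, P(alt | ref/alt) = ½, P(alt | alt/alt) = 1 − ε).
3. **Strand bias** — FS = −10·log₁₀ of the two-sided Fisher exact p-value on
   the ref/alt × forward/reverse read count table must be ≤ 30; one-sided
   pileups are the signature of mapping artifacts.
4. **Geometry** — intronic mismatches within 4 bp of a splice junction are
   removed (spliced-read misalignment); the edit ratio (edited / total RNA
   reads) must lie in [0.10, 0.95], bounds inclusive; sites in repeat regions
   are optionally excluded.
5. **Replication** — only sites detected in *all* biological replicates of a
   tissue are reported as common (reliable) editing sites.

Because bulk RNA-seq is usually unstranded, a genomic T>C mismatch on a
minus-strand gene *is* A-to-G editing: types are relabelled into the
transcript sense-strand alphabet using the gene annotation (sites under
bidirectional transcription stay unassigned). Sites are classified by region
(exonic > splicing > ncRNA > UTR5 > UTR3 > intronic > intergenic precedence),
and exonic sites get codon-level consequences (synonymous / nonsynonymous /
stop-gain / stop-loss with the amino-acid change, e.g. the classic Y→C and
K→R recoding edits).

The `synthetic_data` module generates the entire input side — reference
FASTA, GFF3 gene models, heterozygous DNA SNVs, injected editing events with
known type/strand/edit ratio, and Poisson/Binomial pileup counts with
sequencing error — so sensitivity and specificity can be measured against
known truth. See `docs/methods.md` for the model and its limitations.

## Worked example

```bash
cat > config.yaml <<EOF
seed: 1
simulation:
  seed: 1
  n_chroms: 1
  chrom_length: 30000
  n_genes: 12
  n_edit_sites: 60
  n_replicates: 3
filters:
  genotyping_error_rate: 0.001
EOF
rddscan run-all -c config.yaml -o out --tissue kidney
```

This simulates one 30 kb chromosome with 12 genes and 60 injected editing
sites, three RNA replicates at 40× against one 25× DNA sample, then runs
detect → annotate → summarize. The log reports per replicate:

```
kidney rep2: 16114 positions evaluated, 695 candidates, 55 PASS
kidney rep3: 16129 positions evaluated, 715 candidates, 54 PASS
```

and `out/summary/report.json` contains (abridged):

```
n_sites: 51      # common editing sites present in all three replicates
n_typed: 39      # sites on single-strand transcripts, entering the type spectrum
n_genes: 11      # distinct genes carrying editing sites (intergenic excluded)
regions: {'exonic': 15, 'intronic': 12, 'intergenic': 12, 'UTR5': 6, 'UTR3': 6}
top types: [('A-to-G', 11), ('C-to-A', 5), ('G-to-A', 4), ('G-to-T', 4)]
per-replicate PASS: {'rep1': 53, 'rep2': 55, 'rep3': 54}
aa changing: 13  # nonsynonymous + stop-gain sites
```

Reading: of ~700 candidate positions per replicate (mostly sequencing-error
noise, each rejected with recorded reasons), ~54 pass the full cascade, and
51 replicate across all three animals — the common editing sites. A-to-G
dominates the strand-corrected spectrum because the generator's default type
weights are A-to-I dominated. Per-replicate VCFs, candidate/annotation TSVs
and a common-site VCF are written alongside the report.

The same pipeline is importable as a library (`rddscan.detect_rdds`,
`rddscan.annotate_candidates`, `rddscan.summarize`, …) for use on real
pileup tables.

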