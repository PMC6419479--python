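# Methods

## Detection model

An RNA-DNA difference (RDD) is a genomic position where the DNA sample is
homozygous for the reference base while RNA reads from the same individual
support a different base. Detection operates entirely on per-site, per-strand
allele counts (the pileup TSV schema in `rddscan.io_formats`): per-strand
counts are the minimal sufficient statistics for every filter in the cascade,
so no read-level data (BAM) is required. Mapping quality is assumed to be
applied upstream, when the pileup is constructed; the retained
`frac_mapq_ge` column lets the mapping-quality rule also be asserted
site-level (a site with any sub-threshold covering read is rejected).

### Genotype likelihood

Genotypes are recalled from counts under a per-read substitution model with
error probability ε: a read shows the alternative allele with probability ε
under hom-ref, ½ under het, and 1 − ε under hom-alt. Only reads carrying the
reference or the best-supported alternative enter the likelihood; a second
alternative allele with ≥ `min_alt_reads` support marks the site
multiallelic and disqualifies it (only biallelic SNVs are retained). The
site quality is

    site_qual = −10·log10 P(hom-ref | counts)

under a flat prior over {ref/ref, ref/alt, alt/alt}, capped at 10 000. This
is deliberately the *variant* confidence in all cases (≈ 0 at a clean
hom-ref site): it is the count-level analogue of a haplotype caller's QUAL,
the only quality on a scale where the threshold 95 is meaningful (per-base
phred qualities saturate near 41). The published "base quality ≥ 95" rule is
therefore implemented as `site_qual ≥ 95` on the RNA variant call, with a
separate sanity floor `mean_baseq ≥ 20`; it is *not* reinterpreted as a
percentile.

ε defaults to 0.01 and should be set to the platform's substitution-error
rate; runs on simulated data use the simulator's error rate (10⁻³).

### Fisher strand statistic

FS = −10·log10 of the two-sided Fisher exact p-value on the 2×2 table
(ref, alt) × (forward, reverse), with the standard two-sided convention:
sum the hypergeometric probabilities of all tables with the observed margins
whose probability does not exceed the observed table's. The enumeration is
done in exact integer arithmetic (`math.comb` numerators over a common
denominator), which is both numerically stable and free of tie-breaking
ambiguity — ties at the observed probability are decided exactly, not to
within a floating-point slack. p is clamped to ≥ 1e-300 before the log; an
all-zero table returns FS = 0 by convention. Tables at pipeline depths
(tens to hundreds of reads) cost microseconds.

### Filter cascade

Filters are evaluated in a fixed order without short-circuiting; every
failure is recorded, enabling per-filter attrition tables. Defaults
(`FilterConfig`): DNA depth ≥ 4 with zero alternative DNA reads
(`max_dna_alt_reads = 0`, "completely homozygous" read strictly, but
configurable); RNA depth ≥ 10; alt reads ≥ 2; `frac_mapq_ge = 1` at MAPQ 20;
RNA `site_qual ≥ 95`; mean base quality ≥ 20; FS ≤ 30; intronic sites more
than 4 bp from a splice junction; edit ratio within **[0.10, 0.95], bounds
inclusive** (the rule discards strictly "< 10%" and "> 95%"); optional repeat
exclusion (on by default when a repeat BED is supplied, since repeats are a
known source of mis-mapping, but absent from the core threshold list).

Two points the cascade's sources leave open were decided as follows:

* **RNA heterozygosity: caller vs ratio band.** The RNA site must be a
  *variant* (non-hom-ref genotype call, biallelic); whether it is het or
  hom-alt is left to the edit-ratio band. A maximum-likelihood caller labels
  observed ratios ≳ 0.9 hom-alt, which would silently discard genuine
  high-ratio edits that the band deliberately retains (ratios in
  (0.90, 0.95]). Since all failures are recorded anyway, a site outside the
  band shows the `edit_ratio` code — the band governs the recorded reason.
* **Splice filter scope.** Only intronic positions are checked (exonic bases
  adjacent to a junction are untouched), and a position is "intronic" if it
  falls in the intron of *any* overlapping transcript (union over models).
  Junctions are the first and last base of every intron, derived from the
  supplied GFF3 — the only junction source this artifact has.

### Annotation

Strand-corrected typing uses the strand set of transcripts overlapping the
site: {+} keeps the genomic substitution, {−} complements both bases, mixed
or empty sets yield "unassigned" (excluded from the type spectrum — regions
with bidirectional transcription cannot be typed without stranded RNA-seq).
Region classification uses the conventional precedence
exonic (CDS) > splicing > ncRNA > UTR5 > UTR3 > intronic > intergenic; the
hierarchy is a design choice, and the finer UTR/ncRNA classes can be
collapsed for comparison with coarser schemes. Coding consequences build the
affected codon from the spliced CDS in transcript orientation, substitute
the edited base, and translate with the standard genetic code (table 1
only — no mitochondrial code); stop-loss is classified for completeness.
Amino-acid changes are reported as one-letter codes ("Y→C") without a
position index, since toy coordinates are synthetic.

### Replicate intersection

Common editing sites are the exact intersection of per-replicate PASS sets
keyed by (chrom, pos, ref, alt) — a position edited to different bases in
different replicates is not one editing site (a conservative choice; keying
by position alone would merge them). The summary adds the per-site mean edit
ratio across replicates, a convenience beyond the core procedure.

## Synthetic data generator

The generator emulates the data-generating process the cascade assumes:

* **Genome**: uniform random sequence, genes placed left-to-right with
  random intergenic gaps (non-overlapping by construction), strands ~50/50,
  ~20% ncRNA. Protein-coding transcripts carry UTR5/CDS/UTR3 with CDS length
  divisible by 3, written as a clean ORF (ATG, non-stop sense codons, one
  stop) so consequence calls are biologically sensible.
* **Variation**: heterozygous DNA SNVs at `het_snv_rate` (default 10⁻³/bp,
  the order of mammalian heterozygosity), visible in both DNA and RNA —
  they exercise the homozygosity rejection path. Editing events are drawn
  per region (default 35% exonic, 30% intronic, 10%+10% UTRs, 15%
  intergenic) and per sense-strand type (default A-to-I dominated: 40%
  A-to-G, 10% C-to-T, 5% each of the rest), with edit ratios uniform on
  [0.15, 0.90]. On minus-strand transcripts the genomic substitution is the
  reverse complement of the drawn type. Truth sites avoid het-SNV positions
  and intronic positions within the splice buffer (default 4 bp) of a
  junction: the generator's contract is that a *covered* truth site is
  recoverable, and junction-adjacent intronic sites are removed
  deterministically by design.
* **Counts**: per-position depth ~ Poisson (defaults 25× DNA, 40× RNA —
  typical resequencing depths); allele counts follow the diploid genotype,
  with edited reads ~ Binomial(depth, edit ratio) at RNA truth sites;
  substitution errors flip each read to one of the other three bases
  uniformly at `error_rate` (default 10⁻³ ≈ a Q30 platform); reads split
  ~50/50 between strands. RNA covers transcript spans (pre-mRNA, so introns
  are covered and intronic editing is detectable) plus a 10% scatter of
  intergenic background plus ±30 bp windows around intergenic truth sites,
  modelling the unannotated transcription that real intergenic RDDs come
  from. Everything is deterministic per seed (one numpy Generator stream
  per sample).

What the generator does **not** model — and what passing tests therefore do
not show about real data: alignment and mapping artifacts (the very thing
several filters exist for; simulated `frac_mapq_ge` is always 1 and mean
base quality constant at 37), PCR duplicates, strand-biased library
chemistry, expression-level variation (RNA depth is independent of DNA depth
and constant per gene, since the filters operate on counts, not expression),
indels (the input schema is SNV-only, which satisfies "indels removed"
structurally), hyper-edited clusters, and repeat-driven mis-mapping. Recovery
rates on synthetic data are an upper bound on real-data sensitivity.

## Sensitivity under the default study conditions

The acceptance script reports injection-recovery sensitivity of roughly
0.80–0.87 across seeds under the default conditions (3-replicate
intersection, ratios U[0.15, 0.90], RNA 40×, ε = 10⁻³). This is the
cascade's honest operating point, not an implementation defect, and it
decomposes analytically:

* `site_qual ≥ 95` requires ≈ 8 alternative reads at 40× under ε = 10⁻³
  (each alt read adds ≈ 30 phred against hom-ref, each ref read subtracts
  ≈ 3), so true ratios below ~0.25 are frequently lost — the dominant term;
* the inclusive ratio band still loses binomial tails near both ends
  (a ratio-0.15 site at 40× falls below 4 alt reads ~13% of the time, and
  must survive in all three replicates);
* strict DNA homozygosity at 25× with error 10⁻³ rejects ~2.4% of sites
  (1 − 0.999²⁵) because a single DNA error read disqualifies the position.

Deep RNA coverage *raises* the evidence bar per site — the hom-ref reward
from reference reads grows with depth — which is the same behaviour the
thresholds produce on real data. Specificity is the design priority: across
seeds the common set contains zero heterozygous-SNV positions and zero
false positives among tens of thousands of evaluated positions.

## Numerical and interface choices

* Coordinates are 1-based inclusive in all emitted files (GFF3 / pileup /
  VCF convention); BED is 0-based half-open on disk and converted on read.
  Half-open intervals exist only inside the interval index and never leak
  into files.
* Edit-ratio band checks compare IEEE-correctly-rounded quotients against
  the configured bounds, so counts that are exactly on a bound (e.g. 3/30 vs
  0.10) compare equal and are retained.
* Genotype ties (which cannot arise for ε < 0.5 except at zero depth, which
  is a no-call) would be broken deterministically by genotype ordering;
  the best-supported alternative allele is chosen by count, ties broken
  alphabetically.
* The pipeline config is YAML (chosen over TOML for its native nested
  mappings; round-trips losslessly through `PipelineConfig.load/save`).
* Problem sizes: the default toy genome is 2 × 50 kb with 20 genes, which
  puts ~30 k positions per RNA replicate through the cascade — large enough
  for stable rate estimates at three-decimal precision, small enough that
  the full simulation-to-summary path runs in seconds.

## Known limitations

Single-sample VCF output only (no multi-sample or phasing); no BAM/CRAM
input; no joint DNA+RNA statistical model (the DNA and RNA calls are made
independently, as in the count-level cascade being reimplemented); no
cross-species conservation scoring or editing-database lookup; the genotype
caller is diploid and biallelic by design.
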