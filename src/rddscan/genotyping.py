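"""Diploid genotype calls and the Fisher strand-bias statistic.

The caller re-derives a genotype from per-site allele counts under a simple
per-read substitution-error model: with error probability ``epsilon``, a read
shows the alternative allele with probability ``epsilon`` under hom-ref, 0.5
under het, and ``1 - epsilon`` under hom-alt. Among the three genotypes
{ref/ref, ref/alt, alt/alt} (alt = the best-supported non-reference base) the
maximum-likelihood genotype is returned, and the site quality is the
phred-scaled posterior probability of hom-ref under a flat prior — i.e. the
confidence that the site carries a variant. This is the count-level analogue
of the QUAL a haplotype caller reports, which is the only quality on a scale
where a threshold like 95 is meaningful (per-base phred qualities max out
around 41).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .io_formats import PileupSite

#: site qualities are capped here (phred); corresponds to p = 1e-1000
MAX_SITE_QUAL = 10_000.0

_MIN_P = 1e-300


class NoCallError(ValueError):
    """Raised when a genotype is requested for a site with no reads."""


@dataclass
class GenotypeCall:
    """A diploid genotype with phred-scaled variant confidence.

    ``site_qual`` is −10·log10 of the posterior probability that the site is
    homozygous reference (flat prior over the three genotypes considered),
    capped at :data:`MAX_SITE_QUAL`; ``fs`` is the phred-scaled two-sided
    Fisher exact p-value on the ref/alt × forward/reverse table.
    ``is_biallelic`` is False when a second non-reference allele reaches the
    read-support threshold.
    """

    genotype: Tuple[str, str]
    site_qual: float
    alt_base: Optional[str]
    alt_reads: int
    ref_reads: int
    fs: float
    is_biallelic: bool

    @property
    def is_hom_ref(self) -> bool:
        a, b = self.genotype
        return a == b and self.alt_base != a

    @property
    def is_het(self) -> bool:
        a, b = self.genotype
        return a != b

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.genotype
        return a == b and self.alt_base == a


def fisher_strand(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """Phred-scaled two-sided Fisher exact p-value for strand bias.

    The 2×2 table is (ref, alt) × (forward, reverse). The two-sided p-value
    sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding the observed table's probability — evaluated
    in exact integer arithmetic (``math.comb``), so ties at the observed
    probability are handled exactly. Returns ``-10·log10(p)`` with p clamped
    to >= 1e-300; an all-zero table returns 0 by convention.
    """
    for c in (ref_fwd, ref_rev, alt_fwd, alt_rev):
        if c < 0:
            raise ValueError("counts must be >= 0")
    r1 = ref_fwd + ref_rev
    r2 = alt_fwd + alt_rev
    c1 = ref_fwd + alt_fwd
    n = r1 + r2
    if n == 0:
        return 0.0
    # support of the upper-left cell given the margins
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    num_obs = math.comb(r1, ref_fwd) * math.comb(r2, alt_fwd)
    total = 0
    for a in range(lo, hi + 1):
        num = math.comb(r1, a) * math.comb(r2, c1 - a)
        if num <= num_obs:
            total += num
    p = total / math.comb(n, c1)
    p = min(max(p, _MIN_P), 1.0)
    return -10.0 * math.log10(p)


def call_genotype(
    site: PileupSite,
    error_rate: float = 0.01,
    min_alt_reads: int = 2,
) -> GenotypeCall:
    """Maximum-likelihood diploid genotype from a pileup site.

    Only reads carrying the reference or the best-supported alternative base
    enter the likelihood; additional alleles only affect the biallelic flag.
    Raises :class:`NoCallError` at depth 0.
    """
    if site.depth < 1:
        raise NoCallError(f"no reads at {site.chrom}:{site.pos}")
    ref = site.ref_base
    ref_reads = site.count(ref)
    nonref = site.nonref_bases()
    if not nonref:
        return GenotypeCall(
            genotype=(ref, ref),
            site_qual=_qual_from_posterior(
                _posterior_hom_ref(ref_reads, 0, error_rate)
            ),
            alt_base=None,
            alt_reads=0,
            ref_reads=ref_reads,
            fs=0.0,
            is_biallelic=True,
        )
    alt, alt_reads = nonref[0]
    is_biallelic = not (len(nonref) > 1 and nonref[1][1] >= min_alt_reads)

    eps = error_rate
    n = ref_reads + alt_reads
    k = alt_reads
    # log-likelihoods under the three genotypes (binomial coefficient cancels)
    ll = {
        (ref, ref): k * math.log(eps) + (n - k) * math.log1p(-eps),
        tuple(sorted((ref, alt))): n * math.log(0.5),
        (alt, alt): k * math.log1p(-eps) + (n - k) * math.log(eps),
    }
    genotype = max(ll, key=lambda g: (ll[g], g))
    site_qual = _qual_from_posterior(_posterior_from_ll(ll, (ref, ref)))

    rf, rr = site.strand_counts(ref)
    af, ar = site.strand_counts(alt)
    fs = fisher_strand(rf, rr, af, ar)
    return GenotypeCall(
        genotype=genotype,
        site_qual=site_qual,
        alt_base=alt,
        alt_reads=alt_reads,
        ref_reads=ref_reads,
        fs=fs,
        is_biallelic=is_biallelic,
    )


def is_strictly_homozygous(
    site: PileupSite, call: GenotypeCall, max_dna_alt_reads: int = 0
) -> bool:
    """True iff the genotype is hom-ref and the total non-reference read count
    does not exceed ``max_dna_alt_reads`` ("completely homozygous" at 0)."""
    hom_ref = call.genotype == (site.ref_base, site.ref_base) and not call.is_hom_alt
    return hom_ref and site.nonref_count() <= max_dna_alt_reads


def _posterior_hom_ref(ref_reads: int, alt_reads: int, eps: float) -> float:
    ll = {
        "RR": alt_reads * math.log(eps) + ref_reads * math.log1p(-eps),
        "RA": (ref_reads + alt_reads) * math.log(0.5),
        "AA": alt_reads * math.log1p(-eps) + ref_reads * math.log(eps),
    }
    return _posterior_from_ll(ll, "RR")


def _posterior_from_ll(ll: dict, hom_ref_key) -> float:
    m = max(ll.values())
    weights = {g: math.exp(v - m) for g, v in ll.items()}
    return weights[hom_ref_key] / sum(weights.values())


def _qual_from_posterior(post_hom_ref: float) -> float:
    if post_hom_ref <= 0.0:
        return MAX_SITE_QUAL
    return min(-10.0 * math.log10(post_hom_ref), MAX_SITE_QUAL)
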