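"""Bayesian genotype calling for SNV sites and haplotype-allele loci.

The model is a standard pileup caller. Each base call with Phred quality
q (capped at ``max_base_quality``) has error probability e = 10^(-q/10).
For SNV alleles, P(b | a) = 1-e when b = a and e/3 otherwise. For
haplotype alleles of the same length as the observed call, the
conditional probability is the product of per-base success/error
probabilities in an ungapped alignment; a call and allele of different
lengths get a fixed low indel error probability (0.0001 by default).
Diploid genotype likelihoods average the two allele conditionals per
read; the prior places mass 1-h on the homozygous-reference genotype and
spreads the heterozygosity mass h uniformly over the remaining
genotypes. The call is the maximum-posterior genotype and GQ is the
Phred-scaled probability that it is wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core import GenotypeCall
from .haplotype_clustering import RepresentativeHaplotype
from .realignment import CandidateHaplotype

BASES = "ACGT"
MAX_GQ = 255


@dataclass
class GenotypeModelConfig:
    heterozygosity_prior: float = 0.001
    indel_error_probability: float = 0.0001
    max_base_quality: int = 30
    ploidy: int = 2

    def __post_init__(self):
        if not 0 < self.heterozygosity_prior < 1:
            raise ValueError("heterozygosity_prior must be in (0,1)")
        if not 0 < self.indel_error_probability < 1:
            raise ValueError("indel_error_probability must be in (0,1)")
        if self.max_base_quality < 1:
            raise ValueError("max_base_quality must be >= 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")


DEFAULT_CONFIG = GenotypeModelConfig()


def error_probability(quality: int, config: GenotypeModelConfig) -> float:
    return 10.0 ** (-min(quality, config.max_base_quality) / 10.0)


def _genotype_space(n_alleles: int, ploidy: int) -> list[tuple[int, int]]:
    """Unordered genotypes over allele indices; haploid as doubled index."""
    if ploidy == 1:
        return [(a, a) for a in range(n_alleles)]
    return [(a, b) for a in range(n_alleles) for b in range(a, n_alleles)]


def _posterior_call(
    log_liks: dict[tuple[int, int], float],
    ref_index: int,
    config: GenotypeModelConfig,
) -> tuple[tuple[int, int], float]:
    """Maximum-posterior genotype and its posterior probability."""
    h = config.heterozygosity_prior
    n_other = len(log_liks) - 1
    log_post = {}
    for g, ll in log_liks.items():
        prior = (1.0 - h) if g == (ref_index, ref_index) else h / n_other
        log_post[g] = ll + math.log(prior)
    m = max(log_post.values())
    total = sum(math.exp(v - m) for v in log_post.values())
    best = min(log_post, key=lambda g: (-log_post[g], g))
    return best, math.exp(log_post[best] - m) / total


def phred_gq(posterior: float) -> int:
    if posterior >= 1.0:
        return MAX_GQ
    return min(MAX_GQ, round(-10.0 * math.log10(max(1.0 - posterior, 1e-300))))


# ---------------------------------------------------------------------------
# SNV model

def snv_genotype(
    ref_base: str,
    base_calls: Sequence[tuple[str, int]],
    config: GenotypeModelConfig = DEFAULT_CONFIG,
    alleles: Sequence[str] | None = None,
) -> tuple[GenotypeCall, list[str]] | None:
    """Genotype a single site from (base, quality) pileup calls.

    Returns (call, alt_alleles); allele_pair indexes [ref] + alt_alleles.
    ``alleles`` restricts the model to a fixed allele set (genotyping
    mode); by default all four bases compete. Returns None on an empty
    pileup (no-call).
    """
    if not base_calls:
        return None
    if alleles is None:
        allele_list = [ref_base] + [b for b in BASES if b != ref_base]
    else:
        allele_list = list(alleles)
    ref_index = allele_list.index(ref_base) if ref_base in allele_list else 0
    n = len(allele_list)

    # per-read conditional P(observed | allele)
    conds = []
    for base, q in base_calls:
        e = error_probability(q, config)
        conds.append([1.0 - e if base == a else e / 3.0 for a in allele_list])

    log_liks: dict[tuple[int, int], float] = {}
    for g in _genotype_space(n, config.ploidy):
        ll = 0.0
        for c in conds:
            ll += math.log((c[g[0]] + c[g[1]]) / 2.0)
        log_liks[g] = ll
    best, posterior = _posterior_call(log_liks, ref_index, config)

    called_bases = {allele_list[best[0]], allele_list[best[1]]}
    alt_alleles = [a for a in allele_list[ref_index:] + allele_list[:ref_index]
                   if a != ref_base and (alleles is not None or a in called_bases)]
    # allele order: reference first, then alts in model order
    ordered = [ref_base] + alt_alleles
    pair = tuple(sorted(ordered.index(allele_list[i]) for i in best))
    depths = tuple(sum(1 for b, _ in base_calls if b == a) for a in ordered)
    call = GenotypeCall(
        allele_pair=pair,  # type: ignore[arg-type]
        gq=phred_gq(posterior),
        depth=len(base_calls),
        allele_depths=depths,
        posterior=posterior,
    )
    return call, alt_alleles


# ---------------------------------------------------------------------------
# Haplotype-allele model

def haplotype_likelihood(
    call: CandidateHaplotype,
    allele: RepresentativeHaplotype | str,
    config: GenotypeModelConfig = DEFAULT_CONFIG,
) -> float:
    """P(observed segment | allele).

    Equal lengths: product over columns of 1-e for matches and e for
    mismatches in the ungapped alignment. Different lengths: the fixed
    indel error probability.
    """
    allele_seq = allele.sequence if isinstance(allele, RepresentativeHaplotype) else allele
    if len(call.sequence) != len(allele_seq):
        return config.indel_error_probability
    p = 1.0
    for b, a, q in zip(call.sequence, allele_seq, call.qualities):
        e = error_probability(q, config)
        p *= (1.0 - e) if b == a else e
    return p


def locus_genotype(
    alleles: Sequence[RepresentativeHaplotype],
    candidate_haplotypes: Sequence[CandidateHaplotype],
    config: GenotypeModelConfig = DEFAULT_CONFIG,
) -> GenotypeCall | None:
    """Genotype a locus over representative-haplotype alleles.

    ``alleles[0]`` must be the reference segment. Returns None on zero
    candidate haplotypes (no-call).
    """
    if not candidate_haplotypes:
        return None
    n = len(alleles)
    conds = [
        [haplotype_likelihood(h, a, config) for a in alleles]
        for h in candidate_haplotypes
    ]
    log_liks: dict[tuple[int, int], float] = {}
    for g in _genotype_space(n, config.ploidy):
        ll = 0.0
        for c in conds:
            ll += math.log((c[g[0]] + c[g[1]]) / 2.0)
        log_liks[g] = ll
    best, posterior = _posterior_call(log_liks, 0, config)
    depths = tuple(
        sum(1 for h in candidate_haplotypes if h.sequence == a.sequence) for a in alleles
    )
    return GenotypeCall(
        allele_pair=best,
        gq=phred_gq(posterior),
        depth=len(candidate_haplotypes),
        allele_depths=depths,
        posterior=posterior,
    )
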