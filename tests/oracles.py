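"""Independent brute-force evaluators used as test oracles.

These deliberately re-derive the genotype model from its definition with
plain products and explicit normalisation -- no shared code with the
production genotyper beyond the configuration object.
"""

from __future__ import annotations

import itertools


def _error(q: int, cap: int) -> float:
    return 10.0 ** (-min(q, cap) / 10.0)


def brute_force_snv_posteriors(ref_base, base_calls, config):
    """Posterior over every diploid (or haploid) genotype of the four bases.

    Returns {(allele_a, allele_b): posterior} with alleles as base strings,
    unordered pairs, summing to 1.
    """
    bases = [ref_base] + [b for b in "ACGT" if b != ref_base]
    if config.ploidy == 1:
        genotypes = [(b, b) for b in bases]
    else:
        genotypes = [(bases[i], bases[j]) for i in range(4) for j in range(i, 4)]
    h = config.heterozygosity_prior
    weights = {}
    for g in genotypes:
        prior = (1 - h) if g == (ref_base, ref_base) else h / (len(genotypes) - 1)
        lik = 1.0
        for b, q in base_calls:
            e = _error(q, config.max_base_quality)
            p_a = (1 - e) if b == g[0] else e / 3
            p_b = (1 - e) if b == g[1] else e / 3
            lik *= (p_a + p_b) / 2
        weights[g] = prior * lik
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def brute_force_haplotype_likelihood(call_seq, call_quals, allele_seq, config):
    if len(call_seq) != len(allele_seq):
        return config.indel_error_probability
    p = 1.0
    for b, a, q in zip(call_seq, allele_seq, call_quals):
        e = _error(q, config.max_base_quality)
        p *= (1 - e) if b == a else e
    return p


def brute_force_locus_posteriors(allele_seqs, haplotypes, config):
    """Posterior over genotypes of haplotype alleles (index pairs);
    allele index 0 is the reference."""
    n = len(allele_seqs)
    if config.ploidy == 1:
        genotypes = [(i, i) for i in range(n)]
    else:
        genotypes = [(i, j) for i in range(n) for j in range(i, n)]
    h = config.heterozygosity_prior
    weights = {}
    for g in genotypes:
        prior = (1 - h) if g == (0, 0) else h / (len(genotypes) - 1)
        lik = 1.0
        for seq, quals in haplotypes:
            pa = brute_force_haplotype_likelihood(seq, quals, allele_seqs[g[0]], config)
            pb = brute_force_haplotype_likelihood(seq, quals, allele_seqs[g[1]], config)
            lik *= (pa + pb) / 2
        weights[g] = prior * lik
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def brute_force_min_clusters(sequences, max_distance):
    """Minimum number of groups covering ``sequences`` such that every
    member of a group is within ``max_distance`` (over the variable
    columns of the whole set) of the group's chosen center sequence."""
    distinct = sorted(set(sequences))
    length = len(distinct[0])
    var_pos = [
        c for c in range(length) if len({s[c] for s in distinct}) > 1
    ]

    def dist(a, b):
        return sum(a[p] != b[p] for p in var_pos)

    full = frozenset(range(len(distinct)))
    covers = []
    for center in distinct:
        covers.append(frozenset(
            i for i, s in enumerate(distinct) if dist(s, center) <= max_distance
        ))
    best = [len(distinct)]

    def search(uncovered, used):
        if used >= best[0]:
            return
        if not uncovered:
            best[0] = used
            return
        target = min(uncovered)
        for cov in covers:
            if target in cov:
                search(uncovered - cov, used + 1)

    search(full, 0)
    return best[0]
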