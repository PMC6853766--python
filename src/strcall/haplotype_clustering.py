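"""Two-level clustering of candidate haplotypes into representative alleles.

Candidate haplotypes collected over an indel locus are first partitioned
by exact length. Length groups with at least MIN_SUBCLUSTER members are
stacked into an ungapped alignment, variable columns are identified, and
second-level clusters are formed greedily by Hamming distance over those
columns. The Hamming consensus of each cluster becomes a representative
haplotype, and the set of representatives (plus the reference segment)
is handed to the Bayesian genotyper as the candidate alleles.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .realignment import CandidateHaplotype

MIN_SUBCLUSTER = 10  # length groups smaller than this skip sub-clustering


@dataclass(frozen=True)
class RepresentativeHaplotype:
    sequence: str
    support: int

    def __post_init__(self):
        if self.support < 0:
            raise ValueError("negative support")


@dataclass
class HaplotypeCluster:
    members: list[CandidateHaplotype]
    variable_positions: list[int]
    consensus: RepresentativeHaplotype


def default_max_distance(length: int) -> int:
    """Hamming radius for sub-clustering.

    The radius must absorb every read whose mismatches against its
    cluster's consensus are plausible sequencing errors, or error-bearing
    reads split off as spurious singleton alleles. For per-base error
    rates up to ~1% a three-sigma binomial bound on the per-read error
    count stays below 3 for segments up to ~60 bp, so the radius is 3
    with a 5%-of-length allowance for longer segments.
    """
    return max(3, math.ceil(0.05 * length))


def cluster_by_length(
    haplotypes: Sequence[CandidateHaplotype],
) -> dict[int, list[CandidateHaplotype]]:
    groups: dict[int, list[CandidateHaplotype]] = {}
    for h in haplotypes:
        groups.setdefault(len(h.sequence), []).append(h)
    return groups


def _hamming(a: str, b: str, positions: Sequence[int] | None = None) -> int:
    if positions is None:
        return sum(x != y for x, y in zip(a, b))
    return sum(a[p] != b[p] for p in positions)


def variable_positions(sequences: Sequence[str]) -> list[int]:
    """Columns of the ungapped alignment with >= 2 distinct bases."""
    if not sequences:
        return []
    length = len(sequences[0])
    out = []
    for col in range(length):
        first = sequences[0][col]
        if any(s[col] != first for s in sequences[1:]):
            out.append(col)
    return out


def subcluster_by_hamming(
    members: Sequence[CandidateHaplotype], max_distance: int | None = None
) -> list[HaplotypeCluster]:
    """Greedy Hamming clustering of an equal-length group.

    Groups below MIN_SUBCLUSTER members form a single cluster. Otherwise
    the most frequent distinct sequence seeds a cluster, absorbing members
    within ``max_distance`` over the variable columns; the procedure
    repeats on the remainder.
    """
    members = list(members)
    if not members:
        return []
    length = len(members[0].sequence)
    if any(len(m.sequence) != length for m in members):
        raise ValueError("subcluster_by_hamming requires equal-length members")
    if len(members) < MIN_SUBCLUSTER:
        return [_make_cluster(members, [])]
    if max_distance is None:
        max_distance = default_max_distance(length)
    var_pos = variable_positions([m.sequence for m in members])
    clusters = []
    remaining = members
    while remaining:
        counts = Counter(m.sequence for m in remaining)
        # most frequent sequence seeds; lexicographic tie-break for determinism
        seed = min(counts, key=lambda s: (-counts[s], s))
        taken = [m for m in remaining if _hamming(m.sequence, seed, var_pos) <= max_distance]
        remaining = [m for m in remaining if _hamming(m.sequence, seed, var_pos) > max_distance]
        clusters.append(_make_cluster(taken, var_pos))
    return clusters


def _make_cluster(members: list[CandidateHaplotype], var_pos: list[int]) -> HaplotypeCluster:
    return HaplotypeCluster(members, var_pos, hamming_consensus(members))


def hamming_consensus(members: Sequence[CandidateHaplotype]) -> RepresentativeHaplotype:
    """Per-column plurality base; ties broken by summed base quality, then
    alphabetically."""
    if not members:
        raise ValueError("consensus of zero members")
    length = len(members[0].sequence)
    out = []
    for col in range(length):
        counts: dict[str, int] = {}
        qual: dict[str, int] = {}
        for m in members:
            b = m.sequence[col]
            counts[b] = counts.get(b, 0) + 1
            qual[b] = qual.get(b, 0) + m.qualities[col]
        out.append(min(counts, key=lambda b: (-counts[b], -qual[b], b)))
    return RepresentativeHaplotype("".join(out), len(members))


def representative_alleles(
    reference_segment: str,
    haplotypes: Sequence[CandidateHaplotype],
    max_distance: int | None = None,
) -> list[RepresentativeHaplotype]:
    """Candidate alleles for a locus: one representative per sub-cluster,
    deduplicated by sequence (support summed), with the reference segment
    always present and listed first."""
    support: dict[str, int] = {reference_segment: 0}
    for group in cluster_by_length(haplotypes).values():
        for cluster in subcluster_by_hamming(group, max_distance):
            seq = cluster.consensus.sequence
            support[seq] = support.get(seq, 0) + cluster.consensus.support
    ref = RepresentativeHaplotype(reference_segment, support.pop(reference_segment))
    rest = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    return [ref] + [RepresentativeHaplotype(seq, n) for seq, n in rest]
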