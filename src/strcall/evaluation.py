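"""Gold-standard construction and haplotype-based VCF comparison.

The gold-standard builder derives pool genotypes for the offspring of
two sequenced haploid parents from the consensus of N independent
pipelines (aligner x caller combinations): a heterozygous call needs a
homozygous variant in one parent from at least ``min_support`` pipelines
with at most ``max_conflict`` pipelines calling any variant at the site
in the other parent; a homozygous call needs the same homozygous variant
in both parents from at least ``min_support`` pipelines.

The comparator clusters phased gold calls by proximity to each other or
to an annotated STR, reconstructs the two true haplotypes of each
cluster, builds every haplotype pair consistent with the nearby test
calls (exhaustively below ``het_limit`` heterozygous calls, greedily
above), and classifies each cluster as true positive, genotyping error
or false negative. Test calls inside confidence regions matching no
cluster are false positives; specificity is reported as false positives
per million basepairs (FPPM) of confidence region, swept over minimum-GQ
thresholds.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .core import GenotypeCall, ReferenceGenome, STRAnnotation, VariantRecord, classify_variant_type

PROXIMITY = 5      # bp: test-call attachment and gold-gold clustering radius
HET_LIMIT = 9      # below this many het test calls, phasing is exhaustive
DEFAULT_GQ_GRID = tuple(range(0, 91, 10))

TRUE_POSITIVE = "true_positive"
GENOTYPING_ERROR = "genotyping_error"
FALSE_NEGATIVE = "false_negative"


# ---------------------------------------------------------------------------
# gold-standard builder

def build_gold_standard(
    parent1_calls: list[list[VariantRecord]],
    parent2_calls: list[list[VariantRecord]],
    min_support: int = 10,
    max_conflict: int = 2,
    sample_id: str = "pool",
) -> list[VariantRecord]:
    """Consensus pool genotypes from per-pipeline haploid parental calls."""
    n = len(parent1_calls)
    if len(parent2_calls) != n:
        raise ValueError("parent call sets must list the same number of pipelines")
    if n < min_support:
        raise ValueError(f"{n} pipelines cannot reach min_support={min_support}")

    hom1 = [_hom_variant_keys(p) for p in parent1_calls]
    hom2 = [_hom_variant_keys(p) for p in parent2_calls]
    var1 = [_variant_intervals(p) for p in parent1_calls]
    var2 = [_variant_intervals(p) for p in parent2_calls]

    candidates = sorted(set().union(*hom1, *hom2))
    emitted_sites: set[tuple[str, int]] = set()
    gold: list[VariantRecord] = []
    for key in candidates:
        seq, pos, ref, alt = key
        if (seq, pos) in emitted_sites:
            continue
        n1 = sum(key in h for h in hom1)
        n2 = sum(key in h for h in hom2)
        n_both = sum(key in h1 and key in h2 for h1, h2 in zip(hom1, hom2))
        footprint = (pos, pos + len(ref) - 1)
        c1 = sum(_overlaps_any(v, seq, footprint) for v in var1)
        c2 = sum(_overlaps_any(v, seq, footprint) for v in var2)
        pair = None
        if n_both >= min_support:
            pair = (1, 1)
        elif n1 >= min_support and c2 <= max_conflict:
            pair = (1, 0)
        elif n2 >= min_support and c1 <= max_conflict:
            pair = (0, 1)
        if pair is None:
            continue
        emitted_sites.add((seq, pos))
        gold.append(VariantRecord(
            seq, pos, ref, [alt], classify_variant_type(ref, [alt]),
            {sample_id: GenotypeCall(pair, gq=99, depth=0, phased=True)},
        ))
    gold.sort(key=lambda v: (v.seq_name, v.position))
    return gold


def _single_call(record: VariantRecord) -> GenotypeCall:
    return next(iter(record.calls.values())) if record.calls else GenotypeCall(None)


def _hom_variant_keys(records: list[VariantRecord]) -> set[tuple]:
    keys = set()
    for r in records:
        call = _single_call(r)
        if call.is_missing or call.is_het or call.is_hom_ref:
            continue
        alt = r.alleles[call.allele_pair[0]]
        keys.add((r.seq_name, r.position, r.ref_allele, alt))
    return keys


def _variant_intervals(records: list[VariantRecord]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        if _single_call(r).is_variant:
            out.setdefault(r.seq_name, []).append((r.position, r.footprint_end))
    for seq in out:
        out[seq].sort()
    return out


def _overlaps_any(intervals: dict[str, list[tuple[int, int]]], seq: str,
                  footprint: tuple[int, int]) -> bool:
    lst = intervals.get(seq, [])
    first, last = footprint
    i = bisect_right(lst, (last, 1 << 30))
    for start, end in lst[max(0, i - 8) : i]:
        if end >= first:
            return True
    return False


# ---------------------------------------------------------------------------
# clustering of gold calls

@dataclass
class GoldCluster:
    seq_name: str
    first: int
    last: int
    variants: list[VariantRecord]
    category: str            # SNV | indel | STR
    zygosity: str            # homozygous | heterozygous
    strs: list[STRAnnotation] = field(default_factory=list)

    def distance_to(self, first: int, last: int) -> int:
        if last < self.first:
            return self.first - last
        if first > self.last:
            return first - self.last
        return 0


@dataclass
class ClusterVerdict:
    cluster: GoldCluster
    verdict: str
    matched_test_calls: list[VariantRecord]
    min_gq_of_matched: int = 0


def _interval_distance(a_first, a_last, b_first, b_last) -> int:
    if a_last < b_first:
        return b_first - a_last
    if b_last < a_first:
        return a_first - b_last
    return 0


def cluster_gold(
    gold_variants: list[VariantRecord],
    strs: list[STRAnnotation] | None = None,
    proximity: int = PROXIMITY,
) -> list[GoldCluster]:
    """Cluster gold calls lying within ``proximity`` of each other or of a
    shared STR. Category precedence: STR over indel over SNV."""
    strs = strs or []
    str_by_seq: dict[str, list[STRAnnotation]] = {}
    for s in strs:
        str_by_seq.setdefault(s.seq_name, []).append(s)
    clusters: list[GoldCluster] = []
    by_seq: dict[str, list[VariantRecord]] = {}
    for v in gold_variants:
        by_seq.setdefault(v.seq_name, []).append(v)
    for seq, variants in by_seq.items():
        variants.sort(key=lambda v: v.position)
        seq_strs = str_by_seq.get(seq, [])
        open_cluster: list[VariantRecord] | None = None
        open_strs: set[STRAnnotation] = set()
        open_end = -1
        for v in variants:
            near = {
                s for s in seq_strs
                if _interval_distance(v.position, v.footprint_end, s.first, s.last) < proximity
            }
            if open_cluster is not None and (
                v.position - open_end < proximity or (near & open_strs)
            ):
                open_cluster.append(v)
                open_strs |= near
                open_end = max(open_end, v.footprint_end)
            else:
                if open_cluster is not None:
                    clusters.append(_finish_cluster(seq, open_cluster, open_strs))
                open_cluster = [v]
                open_strs = set(near)
                open_end = v.footprint_end
        if open_cluster is not None:
            clusters.append(_finish_cluster(seq, open_cluster, open_strs))
    clusters.sort(key=lambda c: (c.seq_name, c.first))
    return clusters


def _finish_cluster(seq: str, variants: list[VariantRecord],
                    strs: set[STRAnnotation]) -> GoldCluster:
    first = min(v.position for v in variants)
    last = max(v.footprint_end for v in variants)
    for s in strs:
        first = min(first, s.first)
        last = max(last, s.last)
    if strs:
        category = "STR"
    elif any(v.is_length_changing for v in variants):
        category = "indel"
    else:
        category = "SNV"
    zygosity = (
        "heterozygous" if any(_single_call(v).is_het for v in variants) else "homozygous"
    )
    return GoldCluster(seq, first, last, variants, category, zygosity,
                       sorted(strs, key=lambda s: s.first))


# ---------------------------------------------------------------------------
# haplotype construction

class PhaseConflictError(ValueError):
    """Variants with overlapping footprints assigned to one haplotype."""


def _apply_to_span(
    genome: ReferenceGenome, seq: str, first: int, last: int,
    variants: list[tuple[int, str, str]],
) -> str:
    """Apply (position, ref_allele, allele) substitutions to the reference
    span [first, last]. Raises PhaseConflictError on overlapping footprints."""
    ref = genome.sequences[seq]
    parts: list[str] = []
    cursor = first
    for pos, ref_allele, allele in sorted(variants):
        if pos < cursor:
            raise PhaseConflictError(f"overlapping variants at {seq}:{pos}")
        parts.append(ref[cursor - 1 : pos - 1])
        parts.append(allele)
        cursor = pos + len(ref_allele)
    if cursor > last + 1:
        raise PhaseConflictError(f"variant footprint extends past span end {last}")
    parts.append(ref[cursor - 1 : last])
    return "".join(parts)


def gold_haplotype_pair(
    cluster: GoldCluster, genome: ReferenceGenome,
    span: tuple[int, int] | None = None,
) -> tuple[str, str]:
    """The two true haplotypes over the cluster span, from phased calls."""
    first, last = span if span is not None else (cluster.first, cluster.last)
    hap_variants: tuple[list, list] = ([], [])
    for v in cluster.variants:
        call = _single_call(v)
        if call.is_missing:
            continue
        if call.is_het and not call.phased and len(cluster.variants) > 1:
            raise ValueError(
                f"unphased heterozygous gold call at {v.seq_name}:{v.position} "
                "in a multi-variant cluster: haplotypes unbuildable"
            )
        for hap in (0, 1):
            allele = v.alleles[call.allele_pair[hap]]
            if allele != v.ref_allele:
                hap_variants[hap].append((v.position, v.ref_allele, allele))
    pair = (
        _apply_to_span(genome, cluster.seq_name, first, last, hap_variants[0]),
        _apply_to_span(genome, cluster.seq_name, first, last, hap_variants[1]),
    )
    return tuple(sorted(pair))  # unordered: gold phasing is arbitrary


def build_test_haplotypes(
    cluster: GoldCluster,
    test_calls: list[VariantRecord],
    genome: ReferenceGenome,
    het_limit: int = HET_LIMIT,
    span: tuple[int, int] | None = None,
    gold_pair: tuple[str, str] | None = None,
) -> set[tuple[str, str]]:
    """Unordered haplotype pairs consistent with the attached test calls.

    Homozygous calls are applied to both haplotypes. With h heterozygous
    calls below ``het_limit`` every 2^(h-1) distinct unordered phase
    assignment is enumerated; otherwise a greedy left-to-right assignment
    keeps each partial haplotype a prefix of a gold haplotype, ties going
    to the first phase. Assignments with overlapping footprints in one
    phase are discarded.
    """
    first, last = span if span is not None else (cluster.first, cluster.last)
    seq = cluster.seq_name
    homs: list[tuple[int, str, str]] = []
    hets: list[tuple[int, str, str]] = []
    for t in test_calls:
        call = _single_call(t)
        if call.is_missing or call.is_hom_ref:
            continue
        a0, a1 = (t.alleles[i] for i in call.allele_pair)
        if call.is_het:
            # one haplotype carries the non-reference allele of the pair
            alt = a1 if a0 == t.ref_allele else (a0 if a1 == t.ref_allele else None)
            if alt is None:
                # het between two non-reference alleles: both sides vary
                hets.append((t.position, t.ref_allele, a0))
                hets.append((t.position, t.ref_allele, a1))
                continue
            hets.append((t.position, t.ref_allele, alt))
        else:
            homs.append((t.position, t.ref_allele, a0))

    hets.sort()
    homs.sort()
    pairs: set[tuple[str, str]] = set()
    if len(hets) < het_limit:
        assignments = itertools.product((0, 1), repeat=max(0, len(hets) - 1))
        for rest in assignments:
            phase_sets: tuple[list, list] = (list(homs), list(homs))
            choices = (0,) + rest
            for het, choice in zip(hets, choices):
                phase_sets[choice].append(het)
            try:
                h0 = _apply_to_span(genome, seq, first, last, phase_sets[0])
                h1 = _apply_to_span(genome, seq, first, last, phase_sets[1])
            except PhaseConflictError:
                continue
            pairs.add(tuple(sorted((h0, h1))))
        return pairs

    # greedy: extend whichever phase keeps both partials prefixes of gold
    if gold_pair is None:
        gold_pair = gold_haplotype_pair(cluster, genome, span=(first, last))
    phase_sets = (list(homs), list(homs))
    for het in hets:
        chosen = None
        for choice in (0, 1):
            trial = (list(phase_sets[0]), list(phase_sets[1]))
            trial[choice].append(het)
            try:
                p0 = _apply_to_span(genome, seq, first, min(last, het[0] + len(het[1]) - 1),
                                    [v for v in trial[0] if v[0] <= het[0]])
                p1 = _apply_to_span(genome, seq, first, min(last, het[0] + len(het[1]) - 1),
                                    [v for v in trial[1] if v[0] <= het[0]])
            except PhaseConflictError:
                continue
            if _prefix_pair_match(p0, p1, gold_pair):
                chosen = choice
                break
        if chosen is None:
            chosen = 0
        phase_sets[chosen].append(het)
    try:
        h0 = _apply_to_span(genome, seq, first, last, phase_sets[0])
        h1 = _apply_to_span(genome, seq, first, last, phase_sets[1])
    except PhaseConflictError:
        return set()
    return {tuple(sorted((h0, h1)))}


def _prefix_pair_match(p0: str, p1: str, gold_pair: tuple[str, str]) -> bool:
    ga, gb = gold_pair
    return (ga.startswith(p0) and gb.startswith(p1)) or (
        ga.startswith(p1) and gb.startswith(p0)
    )


def classify_cluster(
    cluster: GoldCluster,
    test_calls: list[VariantRecord],
    genome: ReferenceGenome,
    het_limit: int = HET_LIMIT,
) -> ClusterVerdict:
    """True positive if some test haplotype pair equals the gold pair;
    genotyping error if calls are present but no pair matches; false
    negative when no test calls are attached."""
    active = [t for t in test_calls if _single_call(t).is_variant]
    if not active:
        return ClusterVerdict(cluster, FALSE_NEGATIVE, [])
    first = min([cluster.first] + [t.position for t in active])
    last = max([cluster.last] + [t.footprint_end for t in active])
    gold_pair = gold_haplotype_pair(cluster, genome, span=(first, last))
    test_pairs = build_test_haplotypes(
        cluster, active, genome, het_limit, span=(first, last), gold_pair=gold_pair
    )
    verdict = TRUE_POSITIVE if gold_pair in test_pairs else GENOTYPING_ERROR
    min_gq = min((_single_call(t).gq for t in active), default=0)
    return ClusterVerdict(cluster, verdict, active, min_gq)


# ---------------------------------------------------------------------------
# comparison report

@dataclass
class ComparisonReport:
    table: pd.DataFrame
    confidence_region_bp: int

    def row(self, threshold: int, category: str, zygosity: str) -> pd.Series:
        t = self.table
        sel = t[(t.threshold == threshold) & (t.category == category) & (t.zygosity == zygosity)]
        return sel.iloc[0]


def _in_confidence(conf_index: dict[str, list[tuple[int, int]]], seq: str, pos: int) -> bool:
    lst = conf_index.get(seq, [])
    i = bisect_right(lst, (pos, 1 << 30)) - 1
    return i >= 0 and lst[i][1] >= pos


def compare(
    gold: list[VariantRecord],
    test: list[VariantRecord],
    confidence_regions: list[tuple[str, int, int]],
    strs: list[STRAnnotation] | None = None,
    genome: ReferenceGenome | None = None,
    gq_grid: tuple[int, ...] = DEFAULT_GQ_GRID,
    proximity: int = PROXIMITY,
    het_limit: int = HET_LIMIT,
) -> ComparisonReport:
    """Cluster-based gold/test comparison swept over minimum-GQ filters."""
    if genome is None:
        raise ValueError("compare requires the reference genome")
    conf_bp = sum(last - first + 1 for _, first, last in confidence_regions)
    if conf_bp == 0:
        raise ValueError("empty confidence regions: FPPM undefined")
    conf_index: dict[str, list[tuple[int, int]]] = {}
    for seq, first, last in confidence_regions:
        conf_index.setdefault(seq, []).append((first, last))
    for seq in conf_index:
        conf_index[seq].sort()

    clusters = cluster_gold(gold, strs, proximity)
    str_list = strs or []
    rows = []
    for threshold in gq_grid:
        filtered = [
            t for t in test
            if _single_call(t).is_variant and _single_call(t).gq >= threshold
        ]
        attached: dict[int, list[VariantRecord]] = {i: [] for i in range(len(clusters))}
        fps: list[VariantRecord] = []
        cl_by_seq: dict[str, list[tuple[int, GoldCluster]]] = {}
        for i, c in enumerate(clusters):
            cl_by_seq.setdefault(c.seq_name, []).append((i, c))
        for t in filtered:
            best = None
            for i, c in cl_by_seq.get(t.seq_name, []):
                d = c.distance_to(t.position, t.footprint_end)
                if d < proximity and (best is None or d < best[0]):
                    best = (d, i)
            if best is not None:
                attached[best[1]].append(t)
            elif _in_confidence(conf_index, t.seq_name, t.position):
                fps.append(t)

        counts: dict[tuple[str, str], dict[str, int]] = {}
        for cat in ("SNV", "indel", "STR"):
            for zyg in ("homozygous", "heterozygous"):
                counts[(cat, zyg)] = {"TP": 0, "FP": 0, "FN": 0, "GE": 0}
        for i, c in enumerate(clusters):
            verdict = classify_cluster(c, attached[i], genome, het_limit)
            key = (c.category, c.zygosity)
            if verdict.verdict == TRUE_POSITIVE:
                counts[key]["TP"] += 1
            elif verdict.verdict == GENOTYPING_ERROR:
                counts[key]["GE"] += 1
            else:
                counts[key]["FN"] += 1
        for t in fps:
            in_str = any(
                s.seq_name == t.seq_name
                and _interval_distance(t.position, t.footprint_end, s.first, s.last) == 0
                for s in str_list
            )
            cat = classify_variant_type(t.ref_allele, t.alt_alleles, in_str=in_str)
            zyg = "heterozygous" if _single_call(t).is_het else "homozygous"
            counts[(cat, zyg)]["FP"] += 1

        for (cat, zyg), c in counts.items():
            denom = c["TP"] + c["FN"] + c["GE"]
            rows.append({
                "threshold": threshold, "category": cat, "zygosity": zyg,
                "TP": c["TP"], "FP": c["FP"], "FN": c["FN"],
                "genotyping_errors": c["GE"],
                "sensitivity": c["TP"] / denom if denom else float("nan"),
                "sensitivity_called": c["TP"] / (c["TP"] + c["FN"])
                if (c["TP"] + c["FN"]) else float("nan"),
                "fppm": c["FP"] / conf_bp * 1e6,
            })
    return ComparisonReport(pd.DataFrame(rows), conf_bp)
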