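"""Gold-standard builder consensus rules and the haplotype-based
cluster comparator."""

import numpy as np
import pytest

from strcall.core import GenotypeCall, ReferenceGenome, STRAnnotation, VariantRecord
from strcall.evaluation import (
    FALSE_NEGATIVE,
    GENOTYPING_ERROR,
    TRUE_POSITIVE,
    build_gold_standard,
    build_test_haplotypes,
    classify_cluster,
    cluster_gold,
    compare,
    gold_haplotype_pair,
)
from strcall.simulator import SimulationConfig, simulate_individual, simulate_reference


def rec(pos, ref, alts, pair, phased=True, gq=99, seq="chr1", sample="s"):
    return VariantRecord(seq, pos, ref, list(alts), "SNV",
                         {sample: GenotypeCall(pair, gq=gq, phased=phased)})


def hom_parent_call(pos, ref, alt, seq="chr1"):
    return rec(pos, ref, [alt], (1, 1), seq=seq)


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(4)
    return ReferenceGenome({"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))})


# ---------------------------------------------------------------------------
# gold-standard builder

def _pipelines(n, records):
    return [list(records) for _ in range(n)]


def test_unanimous_hom_both_parents_gives_hom_gold(genome):
    v = hom_parent_call(100, genome.base("chr1", 100), "T"
                        if genome.base("chr1", 100) != "T" else "A")
    gold = build_gold_standard(_pipelines(12, [v]), _pipelines(12, [v]))
    assert len(gold) == 1
    assert gold[0].call("pool").allele_pair == (1, 1)


def test_eleven_vs_one_conflict_gives_het_gold(genome):
    base = genome.base("chr1", 100)
    v = hom_parent_call(100, base, "T" if base != "T" else "A")
    p1 = _pipelines(11, [v]) + [[]]
    p2 = _pipelines(11, []) + [[rec(100, base, ["G" if base != "G" else "C"], (0, 1))]]
    gold = build_gold_standard(p1, p2)
    assert len(gold) == 1
    assert gold[0].call("pool").is_het
    assert gold[0].call("pool").phased


def test_boundary_support_thresholds(genome):
    base = genome.base("chr1", 100)
    v = hom_parent_call(100, base, "T" if base != "T" else "A")
    conflict = rec(100, base, ["G" if base != "G" else "C"], (1, 1))
    # 10 supporting + 2 conflicting -> het (10>=10, 2<=2)
    gold = build_gold_standard(
        _pipelines(10, [v]) + _pipelines(2, []),
        _pipelines(2, [conflict]) + _pipelines(10, []),
    )
    assert len(gold) == 1 and gold[0].call("pool").is_het
    # 9 supporting -> nothing
    gold = build_gold_standard(_pipelines(9, [v]) + _pipelines(3, []), _pipelines(12, []))
    assert gold == []
    # 10 supporting but 3 conflicting -> nothing
    gold = build_gold_standard(
        _pipelines(10, [v]) + _pipelines(2, []),
        _pipelines(3, [conflict]) + _pipelines(9, []),
    )
    assert gold == []


def test_too_few_pipelines_raise():
    with pytest.raises(ValueError):
        build_gold_standard(_pipelines(9, []), _pipelines(9, []), min_support=10)


# ---------------------------------------------------------------------------
# gold clustering

def test_nearby_snvs_share_one_cluster(genome):
    gold = [rec(100, genome.base("chr1", 100), ["T" if genome.base("chr1", 100) != "T" else "A"], (1, 1)),
            rec(103, genome.base("chr1", 103), ["T" if genome.base("chr1", 103) != "T" else "A"], (1, 1))]
    clusters = cluster_gold(gold, [])
    assert len(clusters) == 1
    assert clusters[0].category == "SNV"


def test_str_category_takes_precedence(genome):
    ann = STRAnnotation("chr1", 105, 120)
    b1, b2 = genome.base("chr1", 101), genome.base("chr1", 124)
    gold = [rec(101, b1, ["T" if b1 != "T" else "A"], (1, 1)),
            rec(124, b2 + genome.base("chr1", 125), [b2], (0, 1))]
    clusters = cluster_gold(gold, [ann])
    assert len(clusters) == 1
    assert clusters[0].category == "STR"
    assert clusters[0].first <= 101 and clusters[0].last >= 125


def test_isolated_hom_variant_is_homozygous_singleton(genome):
    b = genome.base("chr1", 500)
    clusters = cluster_gold([rec(500, b, ["T" if b != "T" else "A"], (1, 1))], [])
    assert len(clusters) == 1
    assert clusters[0].zygosity == "homozygous"


def test_unphased_het_in_multivariant_cluster_rejected(genome):
    b1, b2 = genome.base("chr1", 100), genome.base("chr1", 102)
    gold = [rec(100, b1, ["T" if b1 != "T" else "A"], (0, 1), phased=False),
            rec(102, b2, ["T" if b2 != "T" else "A"], (0, 1), phased=False)]
    (cluster,) = cluster_gold(gold, [])
    with pytest.raises(ValueError, match="unphased"):
        gold_haplotype_pair(cluster, genome)


# ---------------------------------------------------------------------------
# test-haplotype construction

def _singleton_cluster(genome, *records):
    (cluster,) = cluster_gold(list(records), [])
    return cluster


def test_phase_enumeration_counts(genome):
    b1, b2, b3 = (genome.base("chr1", p) for p in (100, 102, 104))
    alts = ["T" if b != "T" else "A" for b in (b1, b2, b3)]
    gold = [rec(100, b1, [alts[0]], (0, 1)), rec(102, b2, [alts[1]], (1, 0)),
            rec(104, b3, [alts[2]], (0, 1))]
    cluster = _singleton_cluster(genome, *gold)
    two = build_test_haplotypes(cluster, gold[:2], genome)
    assert len(two) == 2       # 2^(2-1)
    three = build_test_haplotypes(cluster, gold, genome)
    assert len(three) == 4     # 2^(3-1)
    none_het = build_test_haplotypes(
        cluster, [rec(100, b1, [alts[0]], (1, 1))], genome)
    assert len(none_het) == 1  # no het calls: a single identical pair


def test_overlapping_footprints_in_one_phase_discarded(genome):
    # two deletions overlapping the same bases can only live on opposite phases
    r1 = genome.segment("chr1", 100, 104)
    r2 = genome.segment("chr1", 102, 106)
    gold = [rec(100, r1, [r1[0]], (0, 1)), rec(102, r2, [r2[0]], (0, 1))]
    cluster = _singleton_cluster(genome, *gold)
    pairs = build_test_haplotypes(cluster, gold, genome)
    assert len(pairs) == 1  # only the trans assignment survives


def test_classification_verdicts(genome):
    b = genome.base("chr1", 300)
    alt = "T" if b != "T" else "A"
    gold_rec = rec(300, b, [alt], (0, 1))
    cluster = _singleton_cluster(genome, gold_rec)
    assert classify_cluster(cluster, [gold_rec], genome).verdict == TRUE_POSITIVE
    wrong = rec(300, b, [alt], (1, 1))
    assert classify_cluster(cluster, [wrong], genome).verdict == GENOTYPING_ERROR
    assert classify_cluster(cluster, [], genome).verdict == FALSE_NEGATIVE


def test_greedy_result_is_subset_of_exhaustive(genome):
    rng = np.random.default_rng(8)
    for _ in range(20):
        offsets = rng.integers(2, 5, size=3).cumsum()
        positions = [100] + [100 + int(o) for o in offsets]
        gold = []
        for p in positions:
            b = genome.base("chr1", int(p))
            alt = "ACGT"[("ACGT".index(b) + 1) % 4]
            pair = (0, 1) if rng.random() < 0.5 else (1, 0)
            gold.append(rec(int(p), b, [alt], pair))
        (cluster,) = cluster_gold(gold, [])
        exhaustive = build_test_haplotypes(cluster, gold, genome, het_limit=9)
        greedy = build_test_haplotypes(cluster, gold, genome, het_limit=0)
        assert greedy <= exhaustive


# ---------------------------------------------------------------------------
# full comparison

def test_fppm_definition(genome):
    b = genome.base("chr1", 100)
    alt = "T" if b != "T" else "A"
    gold = [rec(100, b, [alt], (1, 1))]
    # 5 false positives far from the cluster
    fps = []
    for p in range(400, 900, 100):
        bb = genome.base("chr1", p)
        fps.append(rec(p, bb, ["T" if bb != "T" else "A"], (1, 1)))
    report = compare(gold, gold + fps, [("chr1", 1, 2000)], [], genome, gq_grid=(0,))
    total_fp = report.table[report.table.threshold == 0].FP.sum()
    assert total_fp == 5
    fppm = report.table[report.table.threshold == 0].fppm.sum()
    assert fppm == pytest.approx(5 / 2000 * 1e6)


def test_gq_filter_monotone_and_threshold_zero_keeps_all(genome):
    rng = np.random.default_rng(15)
    gold, test = [], []
    for p in range(100, 1900, 60):
        b = genome.base("chr1", p)
        alt = "ACGT"[("ACGT".index(b) + 1) % 4]
        gold.append(rec(p, b, [alt], (1, 1)))
        test.append(rec(p, b, [alt], (1, 1), gq=int(rng.integers(5, 95))))
    report = compare(gold, test, [("chr1", 1, 2000)], [], genome,
                     gq_grid=tuple(range(0, 91, 10)))
    agg = report.table.groupby("threshold")[["TP", "FP"]].sum()
    assert agg.TP.iloc[0] == len(gold)  # threshold 0 retains everything
    assert (agg.TP.diff().dropna() <= 0).all()
    assert (agg.FP.diff().dropna() <= 0).all()


def test_empty_confidence_regions_rejected(genome):
    with pytest.raises(ValueError):
        compare([], [], [], [], genome)


def test_self_comparison_is_perfect():
    cfg = SimulationConfig(seed=19, genome_length=50_000, str_variant_probability=1.0,
                           snv_rate=8e-4, indel_rate=4e-4)
    rng = cfg.rng()
    genome, strs = simulate_reference(cfg, rng)
    truth = [t.record for t in simulate_individual(genome, strs, cfg, rng)]
    report = compare(truth, truth, [("chr1", 1, cfg.genome_length)], strs, genome)
    t = report.table
    assert (t.FP == 0).all()
    assert (t.genotyping_errors == 0).all()
    assert (t.dropna(subset=["sensitivity"]).sensitivity == 1.0).all()
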