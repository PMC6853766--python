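"""Pileup traversal: discovery, genotyping and population modes, output
ordering, streaming memory bound and mode equivalence."""

import numpy as np
import pytest

from strcall.core import GenotypeCall, ReferenceGenome, VariantRecord
from strcall.evaluation import compare
from strcall.pileup_engine import CallerConfig, EngineStats, discover, genotype, multicall
from strcall.simulator import (
    SimulationConfig,
    simulate_dataset,
    simulate_individual,
    simulate_reads,
    simulate_reference,
)

from conftest import make_read


def _sorted_copy(reads):
    return iter([r.copy() for r in reads])


# ---------------------------------------------------------------------------
# discovery

def test_discovery_recovers_planted_snv_and_deletion():
    """A het SNV and a het 2 bp deletion at depth 30 are both discovered
    with the correct genotype (truth known by construction)."""
    rng = np.random.default_rng(0)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
    genome = ReferenceGenome({"chr1": ref})
    snv_pos, del_pos = 200, 400
    alt_base = "ACGT"[("ACGT".index(ref[snv_pos - 1]) + 1) % 4]
    hap0 = ref
    hap1 = ref[: snv_pos - 1] + alt_base + ref[snv_pos : del_pos] + ref[del_pos + 2 :]
    reads = []
    for i in range(120):
        start = int(rng.integers(1, 500))
        if i % 2 == 0:
            reads.append(make_read(start, [("M", 100)], ref[start - 1 : start + 99],
                                   name=f"a{i}"))
        else:
            seq = hap1[start - 1 : start + 99]
            if start <= del_pos < start + 100:
                before = del_pos - start + 1
                if before < 5 or before > 95:
                    continue
                cigar = [("M", before), ("D", 2), ("M", 100 - before)]
                seq = hap1[start - 1 : start - 1 + 100]
            else:
                cigar = [("M", 100)]
                if start > del_pos:
                    seq = ref[start + 1 : start + 101]  # past the deletion: ref frame
            reads.append(make_read(start, cigar, seq, name=f"b{i}"))
    reads.sort(key=lambda r: r.start)
    records = list(discover(iter(reads), genome, None, CallerConfig()))
    by_pos = {r.position: r for r in records}
    assert snv_pos in by_pos
    snv = by_pos[snv_pos]
    assert snv.alt_alleles == [alt_base]
    assert list(snv.calls.values())[0].allele_pair == (0, 1)
    indels = [r for r in records if r.is_length_changing]
    assert len(indels) == 1
    (ind,) = indels
    assert ind.position == del_pos
    assert len(ind.ref_allele) - len(ind.alt_alleles[0]) == 2
    assert list(ind.calls.values())[0].is_het


def test_jittered_str_indel_yields_single_record(small_dataset):
    cfg = SimulationConfig(seed=21, genome_length=40_000, str_variant_probability=1.0,
                           snv_rate=0, indel_rate=0, depth=30, anchor_jitter=True)
    genome, strs, truth, reads, _ = simulate_dataset(cfg)
    records = list(discover(iter(reads), genome, strs, CallerConfig()))
    # exactly one record per planted STR variant, at the repeat's anchor
    assert len(records) == len(truth)
    truth_pos = sorted(t.record.position for t in truth)
    assert sorted(r.position for r in records) == truth_pos


def test_empty_alignments_give_no_records(tiny_genome):
    assert list(discover(iter([]), tiny_genome, None, CallerConfig())) == []


def test_unknown_sequence_raises(tiny_genome):
    read = make_read(1, [("M", 4)], "ACGT", seq_name="chrX")
    with pytest.raises(ValueError, match="chrX"):
        list(discover(iter([read]), tiny_genome, None, CallerConfig()))


def test_output_sorted_and_unique(small_dataset):
    d = small_dataset
    records = list(discover(_sorted_copy(d["reads"]), d["genome"], d["strs"],
                            CallerConfig()))
    keys = [(r.seq_name, r.position, r.ref_allele, tuple(r.alt_alleles)) for r in records]
    assert keys == sorted(keys)
    assert len(keys) == len(set(keys))


def test_streaming_memory_bounded_by_window():
    """On a long contig the engine never holds more than a few windows of
    alignments, independent of contig length."""
    cfg = SimulationConfig(seed=9, genome_length=200_000, depth=50,
                           snv_rate=5e-4, indel_rate=2e-4, str_variant_probability=1.0)
    genome, strs, truth, reads, _ = simulate_dataset(cfg)
    stats = EngineStats()
    list(discover(iter(reads), genome, strs, CallerConfig(), stats=stats))
    assert stats.reads_seen == len(reads)
    # a window of depth-50 coverage holds ~2 * depth alignments
    assert stats.peak_active <= 4 * cfg.depth


# ---------------------------------------------------------------------------
# genotyping mode

def _known(seq, pos, ref, alts, vtype="SNV"):
    return VariantRecord(seq, pos, ref, alts, vtype)


def test_known_variants_coverage_rule(tiny_genome):
    ref = tiny_genome.sequences["chr1"]
    reads = [make_read(s, [("M", 60)], ref[s - 1 : s + 59], name=f"r{s}")
             for s in (1, 20)]
    known = [
        _known("chr1", 30, ref[29], ["T" if ref[29] != "T" else "A"]),
        _known("chr1", 50, ref[49], ["T" if ref[49] != "T" else "A"]),
        _known("chr1", 200, ref[199], ["T" if ref[199] != "T" else "A"]),
    ]
    out = list(genotype(iter(reads), tiny_genome, known, None, CallerConfig(),
                        sample_id="s"))
    assert len(out) == 3
    assert not out[0].call("s").is_missing
    assert not out[1].call("s").is_missing
    assert out[2].call("s").is_missing  # zero coverage -> ./.


def test_known_site_all_reference_emits_hom_ref(small_dataset):
    d = small_dataset
    truth_records = [t.record for t in d["truth"]]
    shifted = []
    ref = d["genome"].sequences["chr1"]
    # fabricate known SNVs at positions with no planted variant
    for pos in (10_000, 20_000, 30_000):
        base = ref[pos - 1]
        alt = "ACGT"[("ACGT".index(base) + 1) % 4]
        shifted.append(_known("chr1", pos, base, [alt]))
    out = list(genotype(_sorted_copy(d["reads"]), d["genome"], shifted, d["strs"],
                        CallerConfig(), sample_id="ind"))
    for rec in out:
        assert rec.call("ind").is_hom_ref


def test_known_indel_with_support_matches_truth(small_dataset):
    d = small_dataset
    known = [t.record for t in d["truth"] if t.category in ("indel", "STR")]
    known_bare = [
        VariantRecord(v.seq_name, v.position, v.ref_allele, list(v.alt_alleles),
                      v.variant_type)
        for v in known
    ]
    out = list(genotype(_sorted_copy(d["reads"]), d["genome"], known_bare, d["strs"],
                        CallerConfig(), sample_id="ind"))
    agree = sum(
        1 for t, g in zip(known, out)
        if tuple(sorted(t.call("ind").allele_pair)) == g.call("ind").allele_pair
    )
    assert agree / len(known) >= 0.95


def test_known_str_reads_supporting_reference_emit_homref():
    cfg = SimulationConfig(seed=31, genome_length=30_000, str_variant_probability=0.0,
                           snv_rate=0, indel_rate=0, depth=30)
    genome, strs, truth, reads, _ = simulate_dataset(cfg)
    assert truth == []
    ann = strs[0]
    pos = ann.first - 1
    ref = genome.sequences["chr1"]
    ref_allele = ref[pos - 1 : pos - 1 + len(ann.motif) + 1]
    known = [_known("chr1", pos, ref_allele, [ref[pos - 1]], "STR")]
    out = list(genotype(iter(reads), genome, known, strs, CallerConfig(), sample_id="ind"))
    assert out[0].call("ind").allele_pair == (0, 0)
    assert out[0].call("ind").gq > 0


# ---------------------------------------------------------------------------
# multicall

def _population_reads(seed, n_samples, **kw):
    cfg = SimulationConfig(seed=seed, genome_length=40_000, str_variant_probability=1.0,
                           snv_rate=4e-4, indel_rate=2e-4, depth=30, **kw)
    rng = cfg.rng()
    genome, strs = simulate_reference(cfg, rng)
    per_sample, truths = {}, {}
    for i in range(n_samples):
        sid = f"s{i + 1}"
        t = simulate_individual(genome, strs, cfg, rng, sample_id=sid)
        reads, _ = simulate_reads(genome, t, cfg, rng, sample_id=sid)
        per_sample[sid] = reads
        truths[sid] = t
    return cfg, genome, strs, per_sample, truths


def test_multicall_single_sample_equals_discover():
    cfg, genome, strs, per_sample, _ = _population_reads(41, 1)
    reads = per_sample["s1"]
    mc = list(multicall({"s1": _sorted_copy(reads)}, genome, strs, CallerConfig()))
    dc = list(discover(_sorted_copy(reads), genome, strs, CallerConfig()))
    assert len(mc) == len(dc)
    for a, b in zip(mc, dc):
        assert (a.position, a.ref_allele, a.alt_alleles) == (b.position, b.ref_allele, b.alt_alleles)
        assert a.calls["s1"].allele_pair == b.calls["s1"].allele_pair


def test_multicall_private_variant_genotyped_across_samples():
    cfg, genome, strs, per_sample, truths = _population_reads(43, 4)
    records = list(multicall({k: _sorted_copy(v) for k, v in per_sample.items()},
                             genome, strs, CallerConfig()))
    assert records, "population discovery found nothing"
    # every record carries one call per sample
    assert all(set(r.calls) == set(per_sample) for r in records)
    # find a variant private to one sample in truth and check the others are 0/0
    by_pos = {r.position: r for r in records}
    checked = 0
    for sid, truth in truths.items():
        for t in truth:
            others = [o for o in truths if o != sid]
            if any(any(v.record.position == t.record.position for v in truths[o])
                   for o in others):
                continue
            rec = by_pos.get(t.record.position)
            if rec is None:
                continue
            owner_variant = rec.calls[sid].is_variant
            others_ref = all(
                rec.calls[o].is_hom_ref or rec.calls[o].is_missing for o in others
            )
            if owner_variant and others_ref:
                checked += 1
    assert checked >= 5


def test_multicall_rejects_zero_samples(tiny_genome):
    with pytest.raises(ValueError):
        list(multicall({}, tiny_genome))


def test_multicall_pools_voting_across_samples():
    """An STR indel jittered differently per sample still produces one
    shared locus for the whole population."""
    cfg, genome, strs, per_sample, truths = _population_reads(47, 3, anchor_jitter=True)
    records = list(multicall({k: _sorted_copy(v) for k, v in per_sample.items()},
                             genome, strs, CallerConfig()))
    str_positions = [r.position for r in records if r.variant_type == "STR"]
    assert len(str_positions) == len(set(str_positions))
    anchors = {s.first - 1 for s in strs}
    assert all(p in anchors for p in str_positions)
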