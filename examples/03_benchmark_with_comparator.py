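"""Benchmark a call set against a phased gold standard.

The comparator clusters gold calls by proximity to each other or to an
annotated STR, rebuilds the two true haplotypes of each cluster from the
phased genotypes, and checks whether any phasing of the nearby test
calls reproduces them. This makes the comparison robust to equivalent
indel representations (a caller may legitimately place an STR indel at a
different position or span than the gold standard).
"""

from strcall.evaluation import compare
from strcall.pileup_engine import CallerConfig, discover
from strcall.simulator import SimulationConfig, simulate_dataset

config = SimulationConfig(seed=11, genome_length=60_000, snv_rate=5e-4,
                          indel_rate=3e-4, str_variant_probability=1.0, depth=30)
genome, strs, truth, reads, _ = simulate_dataset(config)
test_calls = list(discover(iter(reads), genome, strs, CallerConfig()))
gold = [t.record for t in truth]

confidence = [("chr1", 1, config.genome_length)]
report = compare(gold, test_calls, confidence, strs, genome, gq_grid=(0, 30, 60))
print(f"confidence region: {report.confidence_region_bp} bp")
cols = ["threshold", "category", "zygosity", "TP", "FP", "FN",
        "genotyping_errors", "sensitivity", "fppm"]
print(report.table[cols].to_string(index=False))
# sensitivity = TP / (TP + FN + genotyping errors) per category; FPPM is
# false positives per million basepairs of confidence region. Raising the
# minimum-GQ threshold trades sensitivity for specificity.
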