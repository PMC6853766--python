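"""Build a pool gold standard from two haploid parents' pipeline calls.

When a pool of F1 segregants descends from two sequenced haploid
parents, confident pool genotypes follow from the consensus of several
independent pipelines run on each parent: a site homozygous-variant in
one parent (>=10 of 12 pipelines) with almost no conflicting evidence in
the other (<=2 pipelines) must be heterozygous in the pool; the same
homozygous variant in both parents must be homozygous.
"""

from strcall.core import GenotypeCall, VariantRecord
from strcall.evaluation import build_gold_standard


def hom_call(pos, ref, alt):
    return VariantRecord("chr1", pos, ref, [alt], "SNV",
                         {"parent": GenotypeCall((1, 1), gq=99)})


shared = hom_call(1000, "A", "T")     # both parents carry T
private = hom_call(2000, "G", "C")    # only parent 1 carries C
disputed = hom_call(3000, "T", "G")   # parent 1, but 3 pipelines also see
conflict = hom_call(3000, "T", "A")   # something in parent 2

parent1 = [[shared, private, disputed] for _ in range(12)]
parent2 = [[shared] + ([conflict] if i < 3 else []) for i in range(12)]

gold = build_gold_standard(parent1, parent2, min_support=10, max_conflict=2)
for rec in gold:
    call = rec.call("pool")
    kind = "heterozygous" if call.is_het else "homozygous"
    print(f"pos {rec.position}: {rec.ref_allele}->{rec.alt_alleles[0]} {kind}")
print(f"\n{len(gold)} gold records from 3 candidate sites "
      "(the disputed site is dropped: 3 conflicting pipelines > 2 allowed)")
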