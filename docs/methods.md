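# Methods

This note documents the models and procedures implemented in `strcall`,
the parameters that matter, what the simulator does and does not
emulate, and the numerical and design choices made where the design was
open.

## Coordinates and data model

All internal coordinates are 1-based inclusive (SAM/VCF convention);
BED's half-open 0-based intervals are converted at the I/O boundary, and
the conversion is its own inverse. Indels follow the VCF convention:
the record position is the base before the event and ref/alt share that
leading base. An indel's *anchor* is the reference position of the last
base before the inserted/deleted sequence. Alignments are held as
editable CIGARs over immutable read bases, so realignment can never
change the base content of a read.

## Pileup traversal and realignment

The engine streams coordinate-sorted alignments per chromosome, holding
only reads overlapping a sliding window (reads are dropped once their
end falls 10 bp left of the current position; peak memory is therefore
set by local depth, not contig length). Only "interesting" positions are
visited: columns where some read mismatches the reference, indel
anchors, known-STR triggers and deferred loci. Positions where every
read matches the reference cannot produce a discovery record under this
model, so skipping them is exact, and it is what makes a pure-Python
traversal practical.

At an anchor *i*, indel events anchored in (*i*, *i*+*x*] are collected,
with *x* the length of the largest indel anchored at *i* — the smallest
window that always contains every placement of the same event shifted
within *x* bp. A vote picks the best-supported start *j* (ties go to the
leftmost position, matching VCF left-alignment convention). If *j* ≠
*i*, position *i* finishes as SNV-only and the locus is processed when
the traversal reaches *j*, where events are re-collected and re-voted
(the vote can only move rightward, so this terminates). CIGAR rewriting
moves match bases between the two blocks flanking the indel operation;
a shift is *infeasible* when the shrinking flank would vanish, in which
case the alignment is left unmodified, flagged, and excluded from
haplotype extraction — the alignment is never forced. Rewriting
conserves both the read-consuming and reference-consuming totals and is
idempotent.

When known STRs are supplied, any event anchored inside a repeat
(including at the base before its first position) routes the whole
repeat to a single locus anchored at `first − 1`, processed at most
once; the locus end is extended to the repeat end so the complete
repeat is one allele-definition unit. Repeats longer than the read
length are skipped outright — no read can span them with flanks, so no
honest call is possible.

The locus interval is [*j*, *k*] with *k* = end of the largest deletion
plus one (or *j* + 1 with only insertions). Reads fully covering
[*j*−5, *k*+5] contribute their aligned segment over [*j*, *k*]
(insertions anchored inside included) as candidate haplotypes; reads
partially spanning the window have the dangling end soft-clipped to
prevent false allele calls. The 5 bp flank is a fixed constant
(`realignment.FLANK`). SNV discovery is suppressed inside a processed
locus [*j*, *k*] — substitutions there are represented in the locus
alleles themselves — and proceeds normally in the flanks.

Genotyping of known variants uses the same machinery with the allele
set fixed by the input record; the locus is the variant footprint plus
one trailing reference base (mirroring the discovery convention so
insertion anchors fall inside the extraction interval), and
homozygous-reference and missing genotypes are emitted. The population
mode merges all samples' reads into one traversal: the indel vote and
the candidate-allele set are computed from the pooled reads, then each
sample is genotyped against the pooled alleles. On a single sample this
reduces exactly to discovery, which is tested.

## Haplotype clustering

Candidate haplotypes are partitioned by exact length. Groups of at
least 10 are stacked into an ungapped alignment; columns with ≥2
distinct bases are the variable positions, and second-level clusters
are grown greedily: the most frequent distinct sequence (lexicographic
tie-break) seeds a cluster and absorbs members within a Hamming radius
over the variable columns; the remainder re-seeds. Groups below 10
members stay a single cluster rather than being discarded, so low-depth
alleles survive. Each cluster's per-column plurality consensus (ties:
higher summed base quality, then alphabetical) becomes a representative
allele; identical representatives merge with summed support, and the
reference segment is always an allele.

The default Hamming radius is `max(3, ceil(0.05·L))` for segment length
L. The radius must absorb reads whose mismatches against their
cluster's consensus are plausible sequencing errors; for per-base error
rates up to ~1%, a 3σ binomial bound on the per-read error count stays
below 3 for segments up to ~60 bp. A tighter radius (e.g. 2% of L)
splits multi-error reads into spurious singleton alleles often enough
to corrupt roughly a third of depth-30 pileups at 1% error. The radius
is configurable per call.

## Genotype model

Per-read error `e = 10^(−min(q, cap)/10)` with the base-quality cap
defaulting to 30 (raising the cap trades heterozygous sensitivity
against false positives, so it is exposed as `--max-bq`). SNV alleles:
`P(b|a) = 1−e` if `b = a`, else `e/3`. Haplotype alleles: for a call of
the same length, the product over columns of `1−eᵢ` (match) or `eᵢ`
(mismatch — deliberately *not* divided by 3, since the alternative at a
haplotype column is "error", not a specific base); for a call of
different length, a fixed indel error probability, default 10⁻⁴.
Diploid genotype likelihood is the product over reads of the mean of
the two allele conditionals; haploid genotypes are the homozygous
diagonal. The prior puts `1−h` on homozygous-reference and splits `h`
(default 0.001) uniformly over every other genotype — a deliberately
flat reconstruction; no Hardy–Weinberg assumption enters anywhere,
which matters for inbred populations. Likelihoods are accumulated in
log space; the exactness of the implementation is checked against an
independent plain-product brute-force evaluator to 1e−12 relative on
randomized pileups of ≤10 reads and ≤3 alleles. GQ is
`round(−10·log₁₀(1−posterior))` capped at 255. No depth or strand-bias
filters are applied: GQ is the single quality predictor, and the
evaluation machinery sweeps it.

Discovery suppresses homozygous-reference loci; genotyping mode emits
them. Allele depths count exact sequence matches to each allele, so
their sum can be below the total depth (ambiguous reads count toward
depth only).

## Gold-standard builder

For a pool descended from two sequenced haploid parents, each of N
pipeline combinations (aligner × caller) yields per-parent calls. A
site becomes a homozygous pool call when ≥`min_support` (default 10 of
12) pipelines call the *same* homozygous variant in both parents, and a
heterozygous call when ≥`min_support` call it homozygous in exactly one
parent while ≤`max_conflict` (default 2) call *any* overlapping variant
in the other. "Any variant at the site" is interpreted as any
overlapping call regardless of allele. Emitted calls are phased
(parent-1 allele first) with GQ 99, and at most one record is emitted
per site.

## Haplotype-based comparison

Gold calls cluster when within 5 bp of each other or of a shared STR
annotation (the same 5 bp radius used to attach test calls; the
published procedure prints only the test-attachment radius). Cluster
category: STR if it touches an annotation, else indel if any gold call
changes length, else SNV; zygosity is heterozygous if any member is.
The cluster's two true haplotypes are built by applying the phased gold
alleles to the reference span (an unphased heterozygous call in a
multi-variant cluster is an error — haplotypes would be ambiguous; a
singleton's phase is immaterial). Test haplotype pairs are built over
the cluster span extended to cover attached test-call footprints:
homozygous calls apply to both haplotypes; `h` heterozygous calls below
the limit of 9 yield all 2^(h−1) unordered phase assignments
(assignments with overlapping footprints in one phase are discarded);
at ≥9 a greedy left-to-right pass extends whichever phase keeps both
partial haplotypes prefixes of the gold pair, ties to the first phase.
Pairs match unordered, since gold phasing is arbitrary relative to test
phasing. Verdicts: true positive if any pair matches, genotyping error
if calls are present but none matches, false negative if no test call
attaches. Test calls inside confidence regions attaching to no cluster
are false positives; FPPM = FP / confidence-region bp × 10⁶. The
report sweeps minimum GQ over 0–90 (default step 10) and carries both
sensitivity definitions — TP/(TP+FN+errors), the headline, and
TP/(TP+FN) — since published curves are ambiguous about the
denominator.

## Family-based genotype QC

Outbred F1: each biallelic variant gets a parental configuration from
the called parent genotypes (or, if a parent call is missing, by
maximum likelihood over offspring genotype frequencies with an
error-tolerant multinomial and a chi-square goodness-of-fit gate at
p > 0.01). Offspring genotypes impossible under the configuration
(e.g. BB under AA×AB, non-AB under AA×BB) are errors; calls at
segregating configurations count as usable. AA×BB is treated as usable
— its forced heterozygosity still validates genotype quality — which
resolves a tension in the source description between "at least one
heterozygous parent" and the worked AA×BB case.

Inbred biparental: over all called genotypes (parents included), the
sensitivity set holds variants with parents homozygous for different
alleles, minor allele frequency > 0.1 and heterozygous fraction < 0.1;
usable calls are the non-missing offspring calls there. Errors are
heterozygous offspring calls inside the set plus minor-allele carriers
at variants with MAF < 0.1. "Expected heterozygosity < 0.1" is read as
the observed heterozygous fraction: under Hardy–Weinberg, MAF > 0.1
forces 2p(1−p) > 0.18, so the literal reading would empty the set; the
observed fraction is the only self-consistent interpretation, and a
`het_mode="hardy_weinberg"` switch exposes the literal statistic
anyway. Missing genotypes are never errors. Sweeps set calls below the
GQ threshold to missing and recompute everything; a grid can be derived
from the observed GQ deciles.

## Simulator

The simulator generates what the method needs to be tested on, not a
full sequencing emulation. References are uniform random DNA with
planted tandem repeats (motif 1–6 bp, total 10–60 bp, ~1 per 5 kbp by
default) whose flanking bases are forced off-motif so annotations are
maximal. Individuals carry phased SNVs, 1–10 bp indels and STR
copy-number changes, spaced ≥150 bp apart (and non-STR variants away
from repeats) so no read spans two variant loci; STR insertion sizes
are capped so the padded locus window still fits within a read. Reads
are emitted pre-aligned (SAM) at uniform positions — mapping is out of
scope — with constant q30 qualities, substitution errors at a given
rate (default 0.001, matching q30), and CIGARs placing each indel at
its true anchor; with `anchor_jitter` the anchor is drawn uniformly
from the legal positions of the containing repeat, modelling mapper
ambiguity. Population designs draw parental configurations, segregate
offspring by Mendelian rules (the F6 design applies five selfing
generations, residual heterozygosity 2⁻⁵), inject genotype errors at a
stated rate into offspring only (parents stay clean so categories stay
anchored), apply missingness, and log every injected error — and, for
the inbred design, every residual-heterozygosity call in the
sensitivity set — with a flag saying whether the family-QC rules can
detect it given the final matrix. Everything is byte-deterministic
under a fixed seed.

What passing tests on this simulator does **not** show: robustness to
mapper-specific soft-clipping and mismapping outside repeats, indel
sequencing-error processes (errors here are substitutions only),
quality-score miscalibration, paired-end effects, uneven coverage
(capture, GBS stacking), or contamination. The simulator's jitter is a
clean model of within-repeat placement ambiguity only.

## Benchmark configurations and problem sizes

The acceptance checks and `scripts/acceptance.py` use preset
configurations chosen to give stable statistics on a single CPU in
minutes: realignment consistency on a 300 kbp genome with ~60 jittered
STR indel loci at depth 30; genotype recovery on 400 kbp with ~200
sites per class (SNV / indel / STR) at depth 30, q30; comparator
self-test on a 100 kbp phased truth set across GQ 0–90; family QC with
100 offspring, 600 variants, 1% injected errors and 5% missingness for
both designs; and 1,000 randomized pileups for the brute-force
likelihood comparison. Measured on these conditions: SNV genotype
concordance ≥99%, indel and STR concordance ≥95% (haplotype-based
matching), every jittered repeat collapsing to a single anchor, exact
agreement between flagged and detectable injected errors, and posterior
agreement with the brute-force oracle within 1e−12 relative.

## Known limitations

* Loci are processed independently; two true variants closer than a
  read length interact only through the locus window, and nested or
  overlapping repeats are merged rather than resolved.
* Large insertions near the read length leave few fully spanning reads;
  a heterozygous insertion whose padded window approaches the read
  length can have no spanning alt read at moderate depth and is then
  (correctly, given the evidence) not called.
* The greedy phasing path needs the gold pair as guidance and is
  deliberately conservative; with ≥9 heterozygous calls in one cluster
  its single candidate pair can miss matches the exhaustive procedure
  would find.
* `multicall` holds one active window per traversal across all samples;
  very deep populations raise memory linearly with total depth.
* No base-quality recalibration, duplicate marking, strand-bias or
  depth filters; CRAM and VCF structural-variant records are out of
  scope.
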