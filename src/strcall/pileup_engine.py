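"""Coordinate-ordered pileup traversal driving realignment, clustering
and genotyping.

Three modes share one streaming engine:

* ``discover``  -- single sample; emits newly found variant records
  (homozygous-reference loci are suppressed).
* ``genotype``  -- single sample against a list of known variants; emits
  one record per known site including homozygous-reference and missing
  genotypes.
* ``multicall`` -- whole population in one pass; indel-start voting and
  allele discovery pool reads across samples, then each sample is
  genotyped against the pooled alleles.

The engine holds only alignments overlapping a sliding window around the
current position, so memory stays bounded by local depth rather than by
contig length. Interesting positions (mismatch columns, indel anchors,
STR triggers, deferred loci) are kept in a heap; positions where every
read agrees with the reference are skipped wholesale, which is what
makes a pure-Python traversal practical.
"""

from __future__ import annotations

import heapq
import itertools
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .core import (
    GenotypeCall,
    ReadAlignment,
    ReferenceGenome,
    STRAnnotation,
    VariantRecord,
    classify_variant_type,
)
from .genotyper import GenotypeModelConfig, locus_genotype, snv_genotype
from .haplotype_clustering import RepresentativeHaplotype, representative_alleles
from .realignment import (
    FLANK,
    IndelLocus,
    clip_or_extract,
    collect_indel_events,
    define_locus,
    indel_events_of,
    shifted_cigar,
    str_exceeds_read_length,
    vote_indel_start,
)

_DROP_MARGIN = 10  # keep reads this far left of the current position


@dataclass
class CallerConfig:
    model: GenotypeModelConfig = field(default_factory=GenotypeModelConfig)
    realign: bool = True


@dataclass
class EngineStats:
    """Counters and per-locus diagnostics filled during a traversal."""

    loci_processed: int = 0
    loci_skipped_long_str: int = 0
    records_emitted: int = 0
    reads_seen: int = 0
    peak_active: int = 0
    # (seq, j, k, distinct unflagged indel anchors after processing, n flagged)
    locus_anchor_summary: list[tuple] = field(default_factory=list)
    realigned_alignments: list[ReadAlignment] | None = None


class _StrIndex:
    """Containing-STR lookup for anchors, over merged annotations."""

    def __init__(self, strs: Sequence[STRAnnotation]):
        self._by_seq: dict[str, list[STRAnnotation]] = {}
        for s in strs or []:
            self._by_seq.setdefault(s.seq_name, []).append(s)
        for seq in self._by_seq:
            self._by_seq[seq].sort(key=lambda s: s.first)
        self._firsts = {seq: [s.first for s in lst] for seq, lst in self._by_seq.items()}

    def containing(self, seq: str, anchor: int) -> STRAnnotation | None:
        lst = self._by_seq.get(seq)
        if not lst:
            return None
        # an anchor at first-1 belongs to the repeat (leading-base convention)
        i = bisect_right(self._firsts[seq], anchor + 1) - 1
        if i >= 0 and lst[i].contains_anchor(anchor):
            return lst[i]
        return None

    def overlapping(self, seq: str, first: int, last: int) -> STRAnnotation | None:
        lst = self._by_seq.get(seq)
        if not lst:
            return None
        i = bisect_right(self._firsts[seq], last) - 1
        if i >= 0 and lst[i].last >= first:
            return lst[i]
        return None


def discover(
    alignments: Iterable[ReadAlignment],
    genome: ReferenceGenome,
    strs: Sequence[STRAnnotation] | None = None,
    config: CallerConfig | None = None,
    stats: EngineStats | None = None,
) -> Iterator[VariantRecord]:
    """Single-sample variant discovery over sorted alignments."""
    yield from _traverse(alignments, genome, strs, config or CallerConfig(),
                         multi_sample=False, stats=stats)


def multicall(
    per_sample_alignments: dict[str, Iterable[ReadAlignment]],
    genome: ReferenceGenome,
    strs: Sequence[STRAnnotation] | None = None,
    config: CallerConfig | None = None,
    stats: EngineStats | None = None,
) -> Iterator[VariantRecord]:
    """Population discovery + genotyping in a single pass.

    Indel voting pools events across all samples; every sample is then
    genotyped against the pooled candidate alleles.
    """
    samples = list(per_sample_alignments)
    if not samples:
        raise ValueError("multicall requires at least one sample")
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample identifiers")
    merged = _merge_sorted(per_sample_alignments, genome)
    yield from _traverse(merged, genome, strs, config or CallerConfig(),
                         multi_sample=True, samples=samples, stats=stats)


def _merge_sorted(
    per_sample: dict[str, Iterable[ReadAlignment]], genome: ReferenceGenome
) -> Iterator[ReadAlignment]:
    order = {name: i for i, name in enumerate(genome.sequences)}
    iters = list(per_sample.values())
    return heapq.merge(*iters, key=lambda a: (order.get(a.seq_name, 1 << 30), a.start))


# ---------------------------------------------------------------------------
# core traversal

def _traverse(
    alignments: Iterable[ReadAlignment],
    genome: ReferenceGenome,
    strs: Sequence[STRAnnotation] | None,
    config: CallerConfig,
    multi_sample: bool,
    samples: list[str] | None = None,
    stats: EngineStats | None = None,
) -> Iterator[VariantRecord]:
    stats = stats if stats is not None else EngineStats()
    str_index = _StrIndex(strs or [])
    for seq_name, group in itertools.groupby(alignments, key=lambda a: a.seq_name):
        if seq_name not in genome:
            raise ValueError(f"alignments reference unknown sequence {seq_name!r}")
        chrom = _ChromTraversal(seq_name, genome, str_index, config, multi_sample,
                                samples, stats)
        yield from chrom.run(group)


class _ChromTraversal:
    def __init__(self, seq_name, genome, str_index, config, multi_sample, samples, stats):
        self.seq = seq_name
        self.genome = genome
        self.ref = genome.sequences[seq_name]
        self.str_index: _StrIndex = str_index
        self.config: CallerConfig = config
        self.multi = multi_sample
        self.samples = samples
        self.stats: EngineStats = stats

        self.active: list[ReadAlignment] = []
        self.heap: list[int] = []
        self.queued: set[int] = set()
        self.anchors: set[int] = set()
        self.mismatch: set[int] = set()
        self.str_trigger: dict[int, STRAnnotation] = {}
        self.deferred: set[int] = set()
        self.processed_strs: set[tuple[int, int]] = set()
        self.suppressed: list[tuple[int, int]] = []
        self.max_read_len = 0

    # -- bookkeeping -------------------------------------------------------

    def _push(self, pos: int) -> None:
        if pos not in self.queued:
            self.queued.add(pos)
            heapq.heappush(self.heap, pos)

    def _add_read(self, aln: ReadAlignment) -> None:
        self.stats.reads_seen += 1
        self.active.append(aln)
        self.max_read_len = max(self.max_read_len, len(aln.bases))
        for ev in indel_events_of(aln):
            containing = self.str_index.containing(self.seq, ev.anchor)
            if containing is not None and self.config.realign:
                j = containing.first - 1
                if (containing.first, containing.last) not in self.processed_strs and j >= 1:
                    self.str_trigger[j] = containing
                    self._push(j)
            else:
                self.anchors.add(ev.anchor)
                self._push(ev.anchor)
        self._register_mismatches(aln)

    def _register_mismatches(self, aln: ReadAlignment) -> None:
        ref_pos = aln.start
        read_pos = 0
        for op, length in aln.cigar:
            if op == "S" or op == "I":
                read_pos += length
            elif op == "D":
                ref_pos += length
            elif op == "M":
                ref_block = self.ref[ref_pos - 1 : ref_pos - 1 + length]
                read_block = aln.bases[read_pos : read_pos + length]
                if ref_block != read_block:
                    for off, (r, b) in enumerate(zip(ref_block, read_block)):
                        if r != b:
                            pos = ref_pos + off
                            self.mismatch.add(pos)
                            self._push(pos)
                ref_pos += length
                read_pos += length

    def _drop_stale(self, pos: int) -> None:
        cutoff = pos - _DROP_MARGIN
        if self.active and self.active[0].end < cutoff:
            self.active = [a for a in self.active if a.end >= cutoff]
        self.stats.peak_active = max(self.stats.peak_active, len(self.active))

    def _is_suppressed(self, pos: int) -> bool:
        self.suppressed = [(s, e) for s, e in self.suppressed if e >= pos - 1]
        return any(s <= pos <= e for s, e in self.suppressed)

    def _spanning(self, pos: int) -> list[ReadAlignment]:
        return [a for a in self.active if a.start <= pos <= a.end]

    # -- main loop ---------------------------------------------------------

    def run(self, reads: Iterator[ReadAlignment]) -> Iterator[VariantRecord]:
        reads = iter(reads)
        nxt = next(reads, None)
        frontier = 0
        while self.heap or nxt is not None:
            while nxt is not None and (not self.heap or nxt.start <= self.heap[0]):
                self._add_read(nxt)
                nxt = next(reads, None)
            if not self.heap:
                continue
            p = heapq.heappop(self.heap)
            self.queued.discard(p)
            if p < frontier:
                continue
            frontier = p
            self._drop_stale(p)
            if p in self.str_trigger:
                ann = self.str_trigger.pop(p)
                key = (ann.first, ann.last)
                if key not in self.processed_strs and not self._is_suppressed(p):
                    self.processed_strs.add(key)
                    yield from self._process_locus(p, str_ann=ann)
                else:
                    self.processed_strs.add(key)
            if (p in self.anchors or p in self.deferred) and not self._is_suppressed(p):
                self.anchors.discard(p)
                self.deferred.discard(p)
                yield from self._process_locus(p, str_ann=None)
            else:
                self.anchors.discard(p)
                self.deferred.discard(p)
            if p in self.mismatch:
                self.mismatch.discard(p)
                if not self._is_suppressed(p):
                    yield from self._snv_site(p)

    # -- indel locus -------------------------------------------------------

    def _process_locus(self, p: int, str_ann: STRAnnotation | None) -> Iterator[VariantRecord]:
        spanning = [a for a in self._spanning(p) if not a.realignment_flagged]
        if str_ann is not None:
            if str_exceeds_read_length(str_ann, self.max_read_len):
                # repeats longer than the reads are excluded from analysis
                self.stats.loci_skipped_long_str += 1
                self.suppressed.append((str_ann.first - 1, str_ann.last))
                return
            events = [e for a in spanning for e in indel_events_of(a)
                      if str_ann.contains_anchor(e.anchor)]
            if not events:
                return
            j = p  # == str_ann.first - 1
        else:
            events = collect_indel_events(spanning, p)
            if not events:
                return
            if self.config.realign:
                j = vote_indel_start(events)
                if j != p:
                    # SNV-only collection finishes at p; the indel locus is
                    # deferred until the traversal reaches j
                    self.deferred.add(j)
                    self._push(j)
                    return
            j = p

        if self.config.realign:
            for ev in events:
                if ev.anchor != j:
                    new_cigar = shifted_cigar(
                        ev.read.cigar, ev.anchor, ev.read.start, ev.kind, ev.length, j
                    )
                    if new_cigar is None:
                        ev.read.realignment_flagged = True
                    else:
                        ev.read.cigar = new_cigar
            if self.stats.realigned_alignments is not None:
                self.stats.realigned_alignments.extend(
                    ev.read for ev in events if ev.anchor != j
                )

        unflagged = [a for a in spanning if not a.realignment_flagged]
        events_j = [e for a in unflagged for e in indel_events_of(a) if e.anchor == j]
        if not events_j and self.config.realign:
            return
        if not self.config.realign:
            events_j = [e for e in events if e.anchor == p]
        locus = define_locus(events_j, j, known_str=str_ann, seq_name=self.seq)
        if locus.window_start < 1 or locus.window_end > len(self.ref):
            return
        self.suppressed.append((locus.start, locus.end))
        self.stats.loci_processed += 1

        haplotypes = []
        for idx, aln in enumerate(self.active):
            if aln.realignment_flagged or aln.end < locus.window_start or aln.start > locus.window_end:
                continue
            hap, new_aln = clip_or_extract(aln, locus)
            if hap is not None:
                haplotypes.append(hap)
            elif new_aln is not aln:
                self.active[idx] = new_aln

        n_anchors = len({e.anchor for a in self.active if not a.realignment_flagged
                         for e in indel_events_of(a)
                         if locus.start <= e.anchor <= locus.end})
        n_flagged = sum(1 for a in self.active if a.realignment_flagged)
        self.stats.locus_anchor_summary.append(
            (self.seq, locus.start, locus.end, n_anchors, n_flagged)
        )
        if not haplotypes:
            return
        ref_segment = self.genome.segment(self.seq, locus.start, locus.end)
        alleles = representative_alleles(ref_segment, haplotypes)
        record = self._genotype_locus(locus, alleles, haplotypes)
        if record is not None:
            self.stats.records_emitted += 1
            yield record

    def _genotype_locus(
        self,
        locus: IndelLocus,
        alleles: list[RepresentativeHaplotype],
        haplotypes: list,
    ) -> VariantRecord | None:
        sample_ids = self.samples if self.multi else sorted({h.sample_id for h in haplotypes})
        calls: dict[str, GenotypeCall] = {}
        called_indices: set[int] = set()
        for sample in sample_ids:
            mine = [h for h in haplotypes if h.sample_id == sample]
            call = locus_genotype(alleles, mine, self.config.model)
            if call is None:
                calls[sample] = GenotypeCall(None)
            else:
                calls[sample] = call
                called_indices.update(call.allele_pair)
        called_indices.discard(0)
        if not called_indices:
            return None  # homozygous reference everywhere: suppressed in discovery
        kept = [0] + sorted(called_indices)
        remap = {old: new for new, old in enumerate(kept)}
        ref_seq = alleles[0].sequence
        alt_seqs = [alleles[i].sequence for i in kept[1:]]
        vtype = classify_variant_type(ref_seq, alt_seqs, in_str=locus.anchored_str is not None)
        out_calls: dict[str, GenotypeCall] = {}
        for sample, call in calls.items():
            if call.is_missing:
                out_calls[sample] = call
                continue
            pair = tuple(sorted(remap[a] for a in call.allele_pair))
            depths = tuple(call.allele_depths[i] for i in kept) if call.allele_depths else ()
            out_calls[sample] = GenotypeCall(pair, call.gq, call.depth, depths, call.posterior)
        return VariantRecord(self.seq, locus.start, ref_seq, alt_seqs, vtype, out_calls)

    # -- SNV site ----------------------------------------------------------

    def _snv_site(self, p: int) -> Iterator[VariantRecord]:
        ref_base = self.ref[p - 1]
        if ref_base == "N":
            return
        per_sample: dict[str, list[tuple[str, int]]] = {}
        for a in self._spanning(p):
            call = a.base_at(p)
            if call is not None:
                per_sample.setdefault(a.sample_id, []).append(call)
        sample_ids = self.samples if self.multi else sorted(per_sample)
        alt_order: list[str] = []
        calls: dict[str, tuple] = {}
        for sample in sample_ids:
            base_calls = per_sample.get(sample, [])
            result = snv_genotype(ref_base, base_calls, self.config.model)
            if result is None:
                calls[sample] = (None, [], [])
                continue
            call, alts = result
            for alt in alts:
                if alt not in alt_order:
                    alt_order.append(alt)
            calls[sample] = (call, alts, base_calls)
        if not alt_order:
            return  # homozygous reference everywhere
        ordered = [ref_base] + sorted(alt_order)
        out_calls: dict[str, GenotypeCall] = {}
        for sample in sample_ids:
            call, alts, base_calls = calls[sample]
            if call is None:
                out_calls[sample] = GenotypeCall(None)
                continue
            local = [ref_base] + alts
            pair = tuple(sorted(ordered.index(local[a]) for a in call.allele_pair))
            depths = tuple(sum(1 for b, _ in base_calls if b == a) for a in ordered)
            out_calls[sample] = GenotypeCall(pair, call.gq, call.depth, depths, call.posterior)
        record = VariantRecord(self.seq, p, ref_base, ordered[1:], "SNV", out_calls)
        self.stats.records_emitted += 1
        yield record


# ---------------------------------------------------------------------------
# genotyping of known variants

def genotype(
    alignments: Iterable[ReadAlignment],
    genome: ReferenceGenome,
    known_variants: Sequence[VariantRecord],
    strs: Sequence[STRAnnotation] | None = None,
    config: CallerConfig | None = None,
    sample_id: str | None = None,
) -> Iterator[VariantRecord]:
    """Genotype a single sample at known variant sites.

    Emits one record per known variant in order, including
    homozygous-reference and missing genotypes.
    """
    config = config or CallerConfig()
    str_index = _StrIndex(strs or [])
    order = {name: i for i, name in enumerate(genome.sequences)}
    known = sorted(known_variants, key=lambda v: (order.get(v.seq_name, 1 << 30), v.position))
    for v in known:
        if v.seq_name not in genome:
            raise ValueError(f"known variant on unknown sequence {v.seq_name!r}")
        if v.footprint_end > genome.length(v.seq_name):
            raise ValueError(f"variant at {v.seq_name}:{v.position} outside reference")

    by_seq: dict[str, list[VariantRecord]] = {}
    for v in known:
        by_seq.setdefault(v.seq_name, []).append(v)

    aln_iter = iter(alignments)
    nxt = next(aln_iter, None)
    for seq_name in genome.sequences:
        variants = by_seq.get(seq_name, [])
        if not variants:
            # skip this chromosome's reads
            while nxt is not None and nxt.seq_name == seq_name:
                nxt = next(aln_iter, None)
            continue
        active: list[ReadAlignment] = []
        for v in variants:
            while nxt is not None and nxt.seq_name == seq_name and nxt.start <= v.footprint_end:
                active.append(nxt)
                if sample_id is None:
                    sample_id = nxt.sample_id
                nxt = next(aln_iter, None)
            cutoff = v.position - len(v.ref_allele) - 2 * FLANK - 60
            active = [a for a in active if a.end >= cutoff]
            yield _genotype_known(v, active, genome, str_index, config,
                                  sample_id or "sample")
        while nxt is not None and nxt.seq_name == seq_name:
            nxt = next(aln_iter, None)


def _genotype_known(
    variant: VariantRecord,
    active: list[ReadAlignment],
    genome: ReferenceGenome,
    str_index: _StrIndex,
    config: CallerConfig,
    sample_id: str,
) -> VariantRecord:
    model = config.model
    out = VariantRecord(
        variant.seq_name, variant.position, variant.ref_allele,
        list(variant.alt_alleles), variant.variant_type, {},
    )
    if len(variant.ref_allele) == 1 and not variant.is_length_changing:
        base_calls = []
        for a in active:
            if a.start <= variant.position <= a.end:
                bc = a.base_at(variant.position)
                if bc is not None:
                    base_calls.append(bc)
        result = snv_genotype(variant.ref_allele, base_calls, model, alleles=variant.alleles)
        out.calls[sample_id] = result[0] if result else GenotypeCall(None)
        return out

    # indel / STR: fixed-allele haplotype genotyping over the variant
    # footprint plus one trailing base, mirroring the discovery locus
    # convention (insertions need an interval that spans their anchor)
    j = variant.position
    end = min(variant.footprint_end + 1, genome.length(variant.seq_name))
    suffix = genome.segment(variant.seq_name, variant.footprint_end + 1, end) \
        if end > variant.footprint_end else ""
    str_ann = str_index.overlapping(variant.seq_name, j, end)
    reach = end + max((len(a) for a in variant.alleles), default=1)
    if str_ann is not None:
        reach = max(reach, str_ann.last)
    if config.realign:
        for a in active:
            if a.realignment_flagged:
                continue
            for ev in indel_events_of(a):
                if ev.anchor != j and j <= ev.anchor <= reach:
                    new_cigar = shifted_cigar(a.cigar, ev.anchor, a.start, ev.kind, ev.length, j)
                    if new_cigar is None:
                        a.realignment_flagged = True
                    else:
                        a.cigar = new_cigar
    locus = IndelLocus(variant.seq_name, j, end, str_ann)
    haplotypes = []
    for a in active:
        if a.realignment_flagged or a.end < locus.window_start or a.start > locus.window_end:
            continue
        hap, _ = clip_or_extract(a, locus)
        if hap is not None:
            haplotypes.append(hap)
    alleles = [RepresentativeHaplotype(s + suffix, 0) for s in variant.alleles]
    call = locus_genotype(alleles, haplotypes, model)
    out.calls[sample_id] = call if call is not None else GenotypeCall(None)
    return out
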