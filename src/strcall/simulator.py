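"""Synthetic data generation for every input the caller touches.

The generator emulates the situations the caller is built for: a
reference with planted tandem repeats, diploid (or haploid) individuals
carrying SNVs, short indels and STR copy-number changes, error-bearing
reads emitted pre-aligned with CIGARs, and biparental population
genotype matrices with injected, individually-logged genotype errors.

Reads are emitted as alignments rather than FASTQ because read mapping
is outside the caller's scope; the ``anchor_jitter`` switch models the
misalignment mappers produce inside repeats by placing each read's indel
anchor uniformly across the containing repeat (keeping the CIGAR legal).
Base qualities are a constant Phred value so tests isolate algorithmic
behaviour from quality modelling.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    GenotypeCall,
    ReadAlignment,
    ReferenceGenome,
    STRAnnotation,
    VariantRecord,
)
from .realignment import FLANK, indel_events_of, shifted_cigar

BASES = "ACGT"


@dataclass
class SimulationConfig:
    seed: int = 1
    genome_length: int = 100_000
    seq_name: str = "chr1"
    # reference repeats
    str_density: float = 1 / 5000
    str_motif_range: tuple[int, int] = (1, 6)
    str_total_range: tuple[int, int] = (10, 60)
    # individual variants
    snv_rate: float = 1e-3
    indel_rate: float = 2e-4
    indel_length_range: tuple[int, int] = (1, 10)
    str_variant_probability: float = 0.5
    min_variant_spacing: int = 150
    ploidy: int = 2
    # reads
    read_length: int = 100
    depth: int = 30
    base_quality: int = 30
    base_error_rate: float = 0.001
    anchor_jitter: bool = False
    # population designs
    population_design: str = "none"  # none | f1_outbred | inbred_f6
    n_offspring: int = 150
    n_population_variants: int = 2000
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.05

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# reference with planted repeats

def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, list[STRAnnotation]]:
    """Random genome with non-overlapping planted tandem repeats.

    Repeats are spaced at least two read lengths apart and their flanking
    bases are forced off-motif so each annotation covers the full repeat.
    """
    rng = rng if rng is not None else config.rng()
    length = config.genome_length
    seq = rng.integers(0, 4, size=length)
    n_strs = round(length * config.str_density)
    margin = 2 * config.read_length
    placed: list[tuple[int, int]] = []  # 0-based [start, end)
    annotations: list[STRAnnotation] = []
    attempts = 0
    while len(annotations) < n_strs and attempts < n_strs * 50:
        attempts += 1
        mlen = int(rng.integers(config.str_motif_range[0], config.str_motif_range[1] + 1))
        total_target = int(rng.integers(config.str_total_range[0], config.str_total_range[1] + 1))
        copies = max(2, total_target // mlen)
        total = copies * mlen
        start = int(rng.integers(margin, length - margin - total))
        if any(start - margin < e and s < start + total + margin for s, e in placed):
            continue
        motif = rng.integers(0, 4, size=mlen)
        if mlen > 1 and len(set(motif.tolist())) == 1:
            motif[rng.integers(0, mlen)] = (motif[0] + 1) % 4
        seq[start : start + total] = np.tile(motif, copies)
        # break the repeat at both flanks so the annotation is maximal
        seq[start - 1] = (motif[-1] + 1 + rng.integers(0, 3)) % 4
        seq[start + total] = (motif[0] + 1 + rng.integers(0, 3)) % 4
        placed.append((start, start + total))
        annotations.append(
            STRAnnotation(config.seq_name, start + 1, start + total,
                          "".join(BASES[b] for b in motif))
        )
    annotations.sort(key=lambda a: a.first)
    genome = ReferenceGenome({config.seq_name: "".join(BASES[b] for b in seq)})
    return genome, annotations


# ---------------------------------------------------------------------------
# individual truth variants

@dataclass
class TruthVariant:
    record: VariantRecord
    category: str  # SNV | indel | STR
    str_annotation: STRAnnotation | None = None


class _Spacer:
    """Rejection sampling helper keeping planted features apart."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self.starts: list[int] = []
        self.ends: list[int] = []

    def blocked(self, first: int, last: int) -> bool:
        i = bisect_left(self.starts, last + self.spacing)
        if i > 0 and self.ends[i - 1] >= first - self.spacing:
            return True
        if i < len(self.starts) and self.starts[i] <= last + self.spacing:
            return True
        return False

    def block(self, first: int, last: int) -> None:
        i = bisect_left(self.starts, first)
        self.starts.insert(i, first)
        self.ends.insert(i, last)


def simulate_individual(
    genome: ReferenceGenome,
    strs: list[STRAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "ind",
) -> list[TruthVariant]:
    """Plant phased SNVs, short indels and STR copy-number variants.

    Variants are spaced at least ``min_variant_spacing`` apart (and away
    from repeats, for non-STR variants) so each read spans at most one
    variant locus. STR alleles never grow past what a read can span.
    """
    rng = rng if rng is not None else config.rng()
    seq_name = config.seq_name
    ref = genome.sequences[seq_name]
    length = len(ref)
    margin = 2 * config.read_length
    spacer = _Spacer(config.min_variant_spacing)
    for s in strs:
        spacer.block(s.first, s.last)

    truth: list[TruthVariant] = []

    def draw_genotype() -> tuple[int, int]:
        if config.ploidy == 1:
            return (1, 1)
        if rng.random() < 0.5:
            return (1, 1)
        return (0, 1) if rng.random() < 0.5 else (1, 0)

    # STR copy-number variants
    for ann in strs:
        if rng.random() >= config.str_variant_probability:
            continue
        mlen = len(ann.motif)
        span = ann.span
        max_ins = config.read_length - 2 * FLANK - span - 20
        insert_ok = max_ins >= mlen
        delete_ok = span - mlen >= mlen  # keep at least one copy
        if not insert_ok and not delete_ok:
            continue
        if insert_ok and (not delete_ok or rng.random() < 0.5):
            copies = int(rng.integers(1, max(1, max_ins // mlen) + 1))
            alt_insert = ann.motif * copies
            pos = ann.first - 1
            ref_allele = ref[pos - 1]
            alt_allele = ref_allele + alt_insert
        else:
            max_del_copies = (span - mlen) // mlen
            copies = int(rng.integers(1, max_del_copies + 1))
            pos = ann.first - 1
            ref_allele = ref[pos - 1 : pos - 1 + copies * mlen + 1]
            alt_allele = ref[pos - 1]
        pair = draw_genotype()
        rec = VariantRecord(
            seq_name, pos, ref_allele, [alt_allele], "STR",
            {sample_id: GenotypeCall(pair, gq=99, phased=True)},
        )
        truth.append(TruthVariant(rec, "STR", ann))

    # SNVs
    n_snv = int(rng.binomial(length, config.snv_rate))
    n_indel = int(rng.binomial(length, config.indel_rate))
    for kind, n in (("SNV", n_snv), ("indel", n_indel)):
        made = 0
        attempts = 0
        while made < n and attempts < n * 80 + 100:
            attempts += 1
            pos = int(rng.integers(margin, length - margin))
            if kind == "SNV":
                first, last = pos, pos
                ref_allele = ref[pos - 1]
                if ref_allele == "N":
                    continue
                alt_allele = BASES[(BASES.index(ref_allele) + 1 + int(rng.integers(0, 3))) % 4]
            else:
                ilen = int(rng.integers(config.indel_length_range[0],
                                        config.indel_length_range[1] + 1))
                if rng.random() < 0.5:  # insertion
                    ref_allele = ref[pos - 1]
                    alt_allele = ref_allele + "".join(
                        BASES[b] for b in rng.integers(0, 4, size=ilen)
                    )
                    first, last = pos, pos + 1
                else:  # deletion
                    ref_allele = ref[pos - 1 : pos - 1 + ilen + 1]
                    alt_allele = ref[pos - 1]
                    first, last = pos, pos + ilen
            if spacer.blocked(first, last):
                continue
            spacer.block(first, last)
            pair = draw_genotype()
            rec = VariantRecord(
                seq_name, pos, ref_allele, [alt_allele], kind,
                {sample_id: GenotypeCall(pair, gq=99, phased=True)},
            )
            truth.append(TruthVariant(rec, kind))
            made += 1

    truth.sort(key=lambda t: t.record.position)
    return truth


# ---------------------------------------------------------------------------
# reads

@dataclass
class _HapSegment:
    kind: str           # M | I | D
    length: int
    hap_start: int      # 0-based position in the haplotype (M/I)
    ref_start: int      # 1-based ref position (M) or anchor (I/D)


def _build_haplotype(
    ref: str, seq_name: str, truth: list[TruthVariant], hap_index: int, sample_id: str
) -> tuple[str, list[_HapSegment], dict[int, STRAnnotation]]:
    """Haplotype sequence plus the segment map aligning it to the reference."""
    parts: list[str] = []
    segments: list[_HapSegment] = []
    jitter_strs: dict[int, STRAnnotation] = {}  # event anchor -> containing STR
    ref_cursor = 1
    hap_cursor = 0
    for t in truth:
        rec = t.record
        call = rec.calls[sample_id]
        allele_idx = call.allele_pair[hap_index if call.is_het else 0]
        if allele_idx == 0:
            continue
        allele = rec.alleles[allele_idx]
        ref_allele = rec.ref_allele
        pos = rec.position
        # matched block up to and including the variant's leading base
        lead = pos - ref_cursor + 1
        if lead > 0:
            segments.append(_HapSegment("M", lead, hap_cursor, ref_cursor))
            parts.append(ref[ref_cursor - 1 : ref_cursor - 1 + lead])
            hap_cursor += lead
            ref_cursor += lead
        if len(ref_allele) == len(allele) == 1:  # SNV: swap the base
            parts[-1] = parts[-1][:-1] + allele
        elif len(allele) > len(ref_allele):  # insertion
            ins = allele[1:]
            segments.append(_HapSegment("I", len(ins), hap_cursor, pos))
            parts.append(ins)
            hap_cursor += len(ins)
            if t.str_annotation is not None:
                jitter_strs[pos] = t.str_annotation
        else:  # deletion
            dlen = len(ref_allele) - len(allele)
            segments.append(_HapSegment("D", dlen, hap_cursor, pos))
            ref_cursor += dlen
            if t.str_annotation is not None:
                jitter_strs[pos] = t.str_annotation
    tail = len(ref) - ref_cursor + 1
    if tail > 0:
        segments.append(_HapSegment("M", tail, hap_cursor, ref_cursor))
        parts.append(ref[ref_cursor - 1 :])
    return "".join(parts), segments, jitter_strs


def _read_cigar(
    segments: list[_HapSegment], hap_start: int, read_length: int
) -> tuple[int, list[tuple[str, int]]] | None:
    """(reference start, CIGAR) for a read at haplotype coords
    [hap_start, hap_start + read_length). Leading/trailing insertions are
    soft-clipped; boundary deletions are dropped."""
    hap_end = hap_start + read_length
    cigar: list[tuple[str, int]] = []
    ref_start = None
    for seg in segments:
        if seg.kind == "D":
            if ref_start is not None and cigar and cigar[-1][0] != "S":
                cigar.append(("D", seg.length))
            continue
        seg_end = seg.hap_start + seg.length
        if seg_end <= hap_start or seg.hap_start >= hap_end:
            continue
        lo = max(seg.hap_start, hap_start)
        hi = min(seg_end, hap_end)
        take = hi - lo
        if seg.kind == "M":
            if ref_start is None:
                ref_start = seg.ref_start + (lo - seg.hap_start)
            cigar.append(("M", take))
        else:  # insertion bases
            cigar.append(("S" if ref_start is None else "I", take))
    if ref_start is None:
        return None
    # trailing D already avoided; trailing I becomes S
    while cigar and cigar[-1][0] == "D":
        cigar.pop()
    if cigar and cigar[-1][0] == "I":
        cigar[-1] = ("S", cigar[-1][1])
    merged: list[tuple[str, int]] = []
    for op, ln in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return ref_start, merged


def simulate_reads(
    genome: ReferenceGenome,
    truth: list[TruthVariant],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "ind",
) -> tuple[list[ReadAlignment], pd.DataFrame]:
    """Coordinate-sorted alignments sampled from the individual's haplotypes.

    Returns the alignments plus a ledger of injected base errors
    (read_name, read_index). With ``anchor_jitter`` the indel anchor of
    every STR-variant-spanning read is placed uniformly across the legal
    anchor positions of the containing repeat.
    """
    rng = rng if rng is not None else config.rng()
    seq_name = config.seq_name
    ref = genome.sequences[seq_name]
    reads: list[ReadAlignment] = []
    errors: list[dict] = []
    n_haps = config.ploidy
    counter = 0
    for hap_index in range(n_haps):
        hap, segments, jitter_strs = _build_haplotype(ref, seq_name, truth, hap_index, sample_id)
        n_reads = round(config.depth * len(hap) / (n_haps * config.read_length))
        starts = np.sort(rng.integers(0, len(hap) - config.read_length, size=n_reads))
        for s in starts:
            s = int(s)
            placed = _read_cigar(segments, s, config.read_length)
            if placed is None:
                continue
            ref_start, cigar = placed
            bases = list(hap[s : s + config.read_length])
            n_err = rng.binomial(config.read_length, config.base_error_rate)
            name = f"r{counter:07d}"
            counter += 1
            if n_err:
                for idx in rng.choice(config.read_length, size=n_err, replace=False):
                    idx = int(idx)
                    old = bases[idx]
                    bases[idx] = BASES[(BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
                    errors.append({"read_name": name, "read_index": idx})
            aln = ReadAlignment(
                read_name=name,
                seq_name=seq_name,
                start=ref_start,
                cigar=cigar,
                bases="".join(bases),
                base_qualities=[config.base_quality] * config.read_length,
                mapping_quality=60,
                sample_id=sample_id,
                reverse_strand=bool(rng.random() < 0.5),
            )
            if config.anchor_jitter:
                _jitter_anchors(aln, jitter_strs, rng)
            aln.validate()
            reads.append(aln)
    reads.sort(key=lambda a: a.start)
    return reads, pd.DataFrame(errors, columns=["read_name", "read_index"])


def _jitter_anchors(
    aln: ReadAlignment, jitter_strs: dict[int, STRAnnotation], rng: np.random.Generator
) -> None:
    """Move each STR indel anchor to a uniform legal position in its repeat."""
    for ev in indel_events_of(aln):
        ann = jitter_strs.get(ev.anchor)
        if ann is None:
            continue
        candidates = []
        for target in range(ann.first - 1, ann.last + 1):
            if target == ev.anchor:
                candidates.append(target)
                continue
            if shifted_cigar(aln.cigar, ev.anchor, aln.start, ev.kind, ev.length, target) is not None:
                candidates.append(target)
        target = int(candidates[rng.integers(0, len(candidates))])
        if target != ev.anchor:
            aln.cigar = shifted_cigar(aln.cigar, ev.anchor, aln.start, ev.kind, ev.length, target)


# ---------------------------------------------------------------------------
# biparental populations

_OUTBRED_CONFIGS = [
    (0, 1), (1, 0), (1, 1), (0, 2), (1, 2), (2, 1),
]  # genotype = alt-allele count: 0=AA, 1=AB, 2=BB

_POSSIBLE_OFFSPRING = {
    (0, 0): {0},
    (0, 1): {0, 1},
    (1, 0): {0, 1},
    (1, 1): {0, 1, 2},
    (0, 2): {1},
    (2, 0): {1},
    (1, 2): {1, 2},
    (2, 1): {1, 2},
    (2, 2): {2},
}


def _cross(parents: tuple[int, int], rng: np.random.Generator, n: int) -> np.ndarray:
    gametes = []
    for g in parents:
        if g == 0:
            gametes.append(np.zeros(n, dtype=int))
        elif g == 2:
            gametes.append(np.ones(n, dtype=int))
        else:
            gametes.append(rng.integers(0, 2, size=n))
    return gametes[0] + gametes[1]


def _self_f6(n: int, rng: np.random.Generator) -> np.ndarray:
    """Genotypes after five selfing generations from a het F1."""
    g = np.ones(n, dtype=int)
    for _ in range(5):
        het = g == 1
        draw = rng.random(het.sum())
        out = np.where(draw < 0.25, 0, np.where(draw < 0.75, 1, 2))
        g[het] = out
    return g


def simulate_population(
    genome: ReferenceGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], list[str], pd.DataFrame]:
    """Multi-sample genotype matrix for a biparental family plus an
    injected-error ledger.

    Parents are error- and missingness-free so population categories stay
    anchored to the truth. Each ledger row logs one injected offspring
    error (or, for the inbred design, one residual-heterozygosity call)
    together with whether the family-QC rules can detect it.
    """
    rng = rng if rng is not None else config.rng()
    design = config.population_design
    if design not in ("f1_outbred", "inbred_f6"):
        raise ValueError(f"unknown population design {design!r}")
    seq_name = config.seq_name
    ref = genome.sequences[seq_name]
    n_var = config.n_population_variants
    n_off = config.n_offspring
    positions = np.sort(
        rng.choice(np.arange(10, len(ref) - 10), size=n_var, replace=False)
    )
    samples = ["P1", "P2"] + [f"F{i + 1:03d}" for i in range(n_off)]

    geno = np.zeros((n_var, n_off), dtype=int)
    parent_geno = np.zeros((n_var, 2), dtype=int)
    truth_geno = np.zeros((n_var, n_off), dtype=int)
    configs: list[tuple[int, int]] = []
    for vi in range(n_var):
        if design == "f1_outbred":
            cfg = _OUTBRED_CONFIGS[int(rng.integers(0, len(_OUTBRED_CONFIGS)))]
            off = _cross(cfg, rng, n_off)
        else:
            cfg = (0, 2) if rng.random() < 0.5 else (2, 0)
            off = _self_f6(n_off, rng)
            if cfg == (2, 0):
                off = 2 - off
        configs.append(cfg)
        parent_geno[vi] = cfg
        truth_geno[vi] = off
    geno[:] = truth_geno

    missing = rng.random((n_var, n_off)) < config.missing_rate
    ledger_rows: list[dict] = []
    err_mask = (rng.random((n_var, n_off)) < config.genotype_error_rate) & ~missing
    for vi, oi in zip(*np.nonzero(err_mask)):
        old = int(geno[vi, oi])
        new = int((old + 1 + rng.integers(0, 2)) % 3)
        geno[vi, oi] = new
        ledger_rows.append({
            "variant_index": int(vi), "position": int(positions[vi]),
            "sample": samples[2 + oi], "kind": "injected",
            "original": old, "observed": new, "detectable": False,
        })

    gq = rng.integers(30, 91, size=(n_var, n_off))
    gq_parents = np.full((n_var, 2), 99, dtype=int)

    # detectability per the family-QC rules, computed from the final matrix
    by_cell = {(r["variant_index"], r["sample"]): r for r in ledger_rows}
    for vi in range(n_var):
        cfg = configs[vi]
        obs = geno[vi]
        miss = missing[vi]
        if design == "f1_outbred":
            possible = _POSSIBLE_OFFSPRING[cfg]
            for oi in range(n_off):
                row = by_cell.get((vi, samples[2 + oi]))
                if row is not None and not miss[oi]:
                    row["detectable"] = int(obs[oi]) not in possible
        else:
            called = obs[~miss]
            n_called = len(called) + 2
            alt_freq = (called.sum() + parent_geno[vi].sum()) / (2 * n_called)
            maf = min(alt_freq, 1 - alt_freq)
            het_frac = ((called == 1).sum() + (parent_geno[vi] == 1).sum()) / n_called
            parents_hom_diff = (
                parent_geno[vi, 0] != parent_geno[vi, 1]
                and parent_geno[vi, 0] in (0, 2)
                and parent_geno[vi, 1] in (0, 2)
            )
            in_sens = parents_hom_diff and maf > 0.1 and het_frac < 0.1
            minor_is_alt = alt_freq <= 0.5
            for oi in range(n_off):
                if miss[oi]:
                    continue
                g = int(obs[oi])
                has_minor = (g >= 1) if minor_is_alt else (g <= 1)
                detectable = (in_sens and g == 1) or (maf < 0.1 and has_minor)
                row = by_cell.get((vi, samples[2 + oi]))
                if row is not None:
                    row["detectable"] = detectable
                elif in_sens and g == 1:
                    ledger_rows.append({
                        "variant_index": vi, "position": int(positions[vi]),
                        "sample": samples[2 + oi], "kind": "residual_het",
                        "original": g, "observed": g, "detectable": True,
                    })

    records: list[VariantRecord] = []
    pair_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    for vi in range(n_var):
        pos = int(positions[vi])
        ref_base = ref[pos - 1]
        if ref_base == "N":
            ref_base = "A"
        alt = BASES[(BASES.index(ref_base) + 1) % 4]
        calls: dict[str, GenotypeCall] = {}
        for pi, name in enumerate(("P1", "P2")):
            calls[name] = GenotypeCall(pair_of[int(parent_geno[vi, pi])],
                                       gq=int(gq_parents[vi, pi]), depth=30)
        for oi in range(n_off):
            if missing[vi, oi]:
                calls[samples[2 + oi]] = GenotypeCall(None)
            else:
                calls[samples[2 + oi]] = GenotypeCall(
                    pair_of[int(geno[vi, oi])], gq=int(gq[vi, oi]), depth=20
                )
        records.append(VariantRecord(seq_name, pos, ref_base, [alt], "SNV", calls))

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["variant_index", "position", "sample", "kind",
                 "original", "observed", "detectable"],
    )
    return records, samples, ledger


# ---------------------------------------------------------------------------
# presets

def preset_indel_jitter(seed: int = 1) -> SimulationConfig:
    """Planted STR indels with anchors jittered across each repeat: the
    realignment-consistency scenario."""
    return SimulationConfig(
        seed=seed, genome_length=300_000, str_density=1 / 4000,
        str_variant_probability=0.8, snv_rate=2e-4, indel_rate=0.0,
        depth=30, anchor_jitter=True,
    )


def preset_genotype_recovery(seed: int = 1) -> SimulationConfig:
    """SNVs, indels and STR variants at matched per-class counts for
    genotype-concordance measurement."""
    return SimulationConfig(
        seed=seed, genome_length=400_000, str_density=1 / 2000,
        str_variant_probability=1.0, snv_rate=5e-4, indel_rate=5e-4,
        depth=30, anchor_jitter=False,
    )


def preset_comparator(seed: int = 1) -> SimulationConfig:
    """Phased truth set over a small genome for comparator self-tests."""
    return SimulationConfig(
        seed=seed, genome_length=100_000, str_density=1 / 5000,
        str_variant_probability=1.0, snv_rate=1e-3, indel_rate=5e-4,
    )


def preset_population_f1(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, genome_length=500_000, population_design="f1_outbred",
        n_offspring=100, n_population_variants=600,
        genotype_error_rate=0.01, missing_rate=0.05,
    )


def preset_population_f6(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, genome_length=500_000, population_design="inbred_f6",
        n_offspring=100, n_population_variants=600,
        genotype_error_rate=0.01, missing_rate=0.05,
    )


PRESETS = {
    "indel-jitter": preset_indel_jitter,
    "genotype-recovery": preset_genotype_recovery,
    "comparator": preset_comparator,
    "population-f1": preset_population_f1,
    "population-f6": preset_population_f6,
}


def simulate_dataset(config: SimulationConfig):
    """One-stop generation: (genome, strs, truth, reads, read_errors).

    Uses a single generator stream so the whole dataset is reproducible
    from the seed alone.
    """
    rng = config.rng()
    genome, strs = simulate_reference(config, rng)
    truth = simulate_individual(genome, strs, config, rng)
    reads, read_errors = simulate_reads(genome, truth, config, rng)
    return genome, strs, truth, reads, read_errors
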