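"""Core domain types shared by every stage of the caller.

Coordinate convention: 1-based inclusive everywhere (SAM/VCF style).
BED's half-open 0-based intervals are converted at the I/O boundary.

CIGAR operations are restricted to the four the pileup needs:
``M`` (match/mismatch, consumes read+reference), ``I`` (insertion, read
only), ``D`` (deletion, reference only) and ``S`` (soft clip, read only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

READ_CONSUMING = {"M", "I", "S"}
REF_CONSUMING = {"M", "D"}
VALID_OPS = {"M", "I", "D", "S"}

MISSING_MQ = 255  # SAM sentinel for "mapping quality unavailable"


class FormatError(ValueError):
    """Raised for malformed or contract-violating input files."""


class ReferenceGenome:
    """An in-memory reference: ordered map of sequence name -> uppercase DNA."""

    def __init__(self, sequences: dict[str, str]):
        names = list(sequences)
        if len(names) != len(set(names)):
            raise FormatError("duplicate sequence names in reference")
        self.sequences: dict[str, str] = {n: s.upper() for n, s in sequences.items()}
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(f"sequence {name} contains non-ACGTN symbols: {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def segment(self, name: str, first: int, last: int) -> str:
        """Reference bases over the 1-based inclusive interval [first, last]."""
        if first < 1 or last > len(self.sequences[name]) or first > last:
            raise ValueError(f"interval [{first},{last}] outside {name}")
        return self.sequences[name][first - 1 : last]

    def base(self, name: str, position: int) -> str:
        return self.segment(name, position, position)


@dataclass(frozen=True)
class STRAnnotation:
    """A known short tandem repeat on the reference, 1-based inclusive."""

    seq_name: str
    first: int
    last: int
    motif: str | None = None

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError(f"STR interval [{self.first},{self.last}] inverted")

    @property
    def span(self) -> int:
        return self.last - self.first + 1

    def contains_anchor(self, anchor: int) -> bool:
        # An insertion at the very start of the repeat is anchored one base
        # before ``first``; such events still belong to the repeat.
        return self.first - 1 <= anchor <= self.last


@dataclass
class ReadAlignment:
    """One aligned read with an editable alignment description (CIGAR).

    Realignment never touches ``bases``; it only rewrites ``cigar`` in
    memory, so the multiset of read bases is conserved by construction.
    """

    read_name: str
    seq_name: str
    start: int  # 1-based leftmost aligned reference position
    cigar: list[tuple[str, int]]
    bases: str
    base_qualities: list[int]
    mapping_quality: int = 60
    sample_id: str = "sample"
    reverse_strand: bool = False
    realignment_flagged: bool = False

    def validate(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.read_name}: start {self.start} < 1")
        for op, length in self.cigar:
            if op not in VALID_OPS or length < 1:
                raise ValueError(f"{self.read_name}: bad CIGAR element {op}{length}")
        consumed = sum(l for op, l in self.cigar if op in READ_CONSUMING)
        if consumed != len(self.bases):
            raise ValueError(
                f"{self.read_name}: CIGAR consumes {consumed} read bases, read has {len(self.bases)}"
            )
        if len(self.base_qualities) != len(self.bases):
            raise ValueError(f"{self.read_name}: quality/base length mismatch")

    @property
    def reference_span(self) -> int:
        return sum(l for op, l in self.cigar if op in REF_CONSUMING)

    @property
    def end(self) -> int:
        """Last 1-based reference position consumed by the alignment."""
        return self.start + self.reference_span - 1

    def base_at(self, position: int) -> tuple[str, int] | None:
        """Aligned (base, quality) at a reference position.

        Returns None when the position falls in a deletion, is soft-clipped,
        or is outside the aligned span.
        """
        ref = self.start
        read = 0
        for op, length in self.cigar:
            if op == "S" or op == "I":
                read += length
            elif op == "M":
                if ref <= position < ref + length:
                    idx = read + (position - ref)
                    return self.bases[idx], self.base_qualities[idx]
                ref += length
                read += length
            elif op == "D":
                if ref <= position < ref + length:
                    return None
                ref += length
        return None

    def copy(self) -> "ReadAlignment":
        return replace(self, cigar=list(self.cigar), base_qualities=list(self.base_qualities))


@dataclass
class GenotypeCall:
    """A called genotype for one sample at one variant.

    ``allele_pair`` indexes into the record's allele list (reference first);
    haploid calls are encoded as a doubled index, missing calls as None.
    """

    allele_pair: tuple[int, int] | None
    gq: int = 0
    depth: int = 0
    allele_depths: tuple[int, ...] = ()
    posterior: float = 0.0
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return self.allele_pair is None

    @property
    def is_het(self) -> bool:
        return self.allele_pair is not None and self.allele_pair[0] != self.allele_pair[1]

    @property
    def is_hom_ref(self) -> bool:
        return self.allele_pair == (0, 0)

    @property
    def is_variant(self) -> bool:
        return self.allele_pair is not None and self.allele_pair != (0, 0)


@dataclass
class VariantRecord:
    """A variant site with per-sample genotype calls (VCF semantics)."""

    seq_name: str
    position: int  # 1-based position of the first reference-allele base
    ref_allele: str
    alt_alleles: list[str]
    variant_type: str = "SNV"  # SNV | indel | STR
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self):
        if not self.ref_allele:
            raise ValueError("empty reference allele")
        seen = {self.ref_allele}
        for alt in self.alt_alleles:
            if alt in seen:
                raise ValueError(f"duplicate allele {alt} at {self.seq_name}:{self.position}")
            seen.add(alt)

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele] + list(self.alt_alleles)

    @property
    def footprint_end(self) -> int:
        """Last reference position covered by the reference allele."""
        return self.position + len(self.ref_allele) - 1

    @property
    def is_length_changing(self) -> bool:
        return any(len(a) != len(self.ref_allele) for a in self.alt_alleles)

    def call(self, sample: str) -> GenotypeCall:
        return self.calls.get(sample, GenotypeCall(None))

    def sort_key(self, seq_order: dict[str, int] | None = None) -> tuple:
        seq = seq_order.get(self.seq_name, 1 << 30) if seq_order else self.seq_name
        return (seq, self.position, self.ref_allele, tuple(self.alt_alleles))


def classify_variant_type(ref: str, alts: list[str], in_str: bool = False) -> str:
    if in_str:
        return "STR"
    if any(len(a) != len(ref) for a in alts):
        return "indel"
    return "SNV"
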