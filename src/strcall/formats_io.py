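"""Reading and writing the standard formats the toolkit touches.

FASTA goes through Bio.SeqIO, SAM/BAM and VCF through pysam. BED and
Tandem Repeats Finder tables are simple line formats parsed here. All
coordinates are converted to the internal 1-based inclusive convention
at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

from .core import (
    MISSING_MQ,
    FormatError,
    GenotypeCall,
    ReadAlignment,
    ReferenceGenome,
    STRAnnotation,
    VariantRecord,
)

DEFAULT_MIN_MQ = 20

_CIGAR_CODE_TO_OP = {0: "M", 1: "I", 2: "D", 3: "D", 4: "S", 7: "M", 8: "M"}
_OP_TO_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


# ---------------------------------------------------------------------------
# FASTA

def read_reference(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA reference, uppercased, order of appearance preserved."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate sequence name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(sequences)


def write_reference(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM / BAM

def read_alignments(
    path: str | os.PathLike,
    min_mapping_quality: int = DEFAULT_MIN_MQ,
    sample_id: str | None = None,
) -> Iterator[ReadAlignment]:
    """Stream mapped primary alignments in coordinate order.

    Unmapped, secondary and supplementary records are skipped, as are
    records below the mapping-quality threshold; an undefined mapping
    quality (255) is treated as passing. Raises FormatError naming the
    first out-of-order record if the file is not coordinate sorted.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        if sample_id is None:
            rgs = sam.header.to_dict().get("RG", [])
            sample_id = rgs[0].get("SM", "sample") if rgs else "sample"
        last: tuple[int, int] | None = None
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            key = (rec.reference_id, rec.reference_start)
            if last is not None and key < last:
                raise FormatError(
                    f"alignments not coordinate-sorted: read {rec.query_name!r} at "
                    f"{rec.reference_name}:{rec.reference_start + 1} follows a later record"
                )
            last = key
            mq = rec.mapping_quality
            if mq != MISSING_MQ and mq < min_mapping_quality:
                continue
            yield _from_pysam(rec, sample_id)


def _from_pysam(rec: pysam.AlignedSegment, sample_id: str) -> ReadAlignment:
    cigar: list[tuple[str, int]] = []
    for code, length in rec.cigartuples or []:
        if code == 5:  # hard clip: consumes nothing we track
            continue
        op = _CIGAR_CODE_TO_OP.get(code)
        if op is None:
            raise FormatError(f"unsupported CIGAR operation code {code} in read {rec.query_name}")
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))
    quals = list(rec.query_qualities) if rec.query_qualities is not None else [30] * len(rec.query_sequence)
    aln = ReadAlignment(
        read_name=rec.query_name,
        seq_name=rec.reference_name,
        start=rec.reference_start + 1,
        cigar=cigar,
        bases=rec.query_sequence.upper(),
        base_qualities=quals,
        mapping_quality=rec.mapping_quality,
        sample_id=sample_id,
        reverse_strand=rec.is_reverse,
    )
    aln.validate()
    return aln


def write_alignments(
    alignments: Iterable[ReadAlignment],
    genome: ReferenceGenome,
    path: str | os.PathLike,
    sample_ids: list[str] | None = None,
) -> None:
    """Write alignments as SAM with @SQ lines from the genome and @RG per sample."""
    alignments = list(alignments)
    if sample_ids is None:
        sample_ids = sorted({a.sample_id for a in alignments}) or ["sample"]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in genome.sequences.items()],
        "RG": [{"ID": s, "SM": s} for s in sample_ids],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_name
            rec.reference_name = aln.seq_name
            rec.reference_start = aln.start - 1
            rec.mapping_quality = aln.mapping_quality
            rec.cigartuples = [(_OP_TO_CIGAR_CODE[op], l) for op, l in aln.cigar]
            rec.query_sequence = aln.bases
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 93) + 33) for q in aln.base_qualities)
            )
            rec.flag = 16 if aln.reverse_strand else 0
            rec.set_tag("RG", aln.sample_id)
            out.write(rec)


# ---------------------------------------------------------------------------
# STR annotations (BED / Tandem Repeats Finder)

def read_str_annotations(
    path: str | os.PathLike,
    dialect: str = "bed",
    genome: ReferenceGenome | None = None,
) -> list[STRAnnotation]:
    """Parse STR annotations from BED or a Tandem Repeats Finder .dat table.

    BED half-open 0-based intervals are converted to 1-based inclusive;
    overlapping annotations on one sequence are merged into one interval.
    """
    if dialect == "bed":
        raw = _parse_bed_strs(path)
    elif dialect == "trf":
        raw = _parse_trf(path)
    else:
        raise ValueError(f"unknown STR dialect {dialect!r}")
    if genome is not None:
        for ann in raw:
            if ann.seq_name not in genome:
                raise FormatError(f"STR annotation on unknown sequence {ann.seq_name!r}")
            if ann.first < 1 or ann.last > genome.length(ann.seq_name):
                raise FormatError(
                    f"STR [{ann.first},{ann.last}] outside {ann.seq_name} "
                    f"(length {genome.length(ann.seq_name)})"
                )
    return merge_str_annotations(raw)


def _parse_bed_strs(path) -> list[STRAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 fields")
            motif = fields[3] if len(fields) > 3 and fields[3] != "." else None
            out.append(STRAnnotation(fields[0], int(fields[1]) + 1, int(fields[2]), motif))
    return out


def _parse_trf(path) -> list[STRAnnotation]:
    """Tandem Repeats Finder .dat: 'Sequence:' headers, then rows whose first
    two fields are the 1-based start and end and whose 14th is the motif."""
    out = []
    seq_name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("Sequence:"):
                seq_name = line.split(None, 1)[1].split()[0]
                continue
            fields = line.split()
            if len(fields) >= 14 and fields[0].isdigit() and fields[1].isdigit():
                if seq_name is None:
                    raise FormatError(f"{path}: TRF data row before any 'Sequence:' header")
                out.append(STRAnnotation(seq_name, int(fields[0]), int(fields[1]), fields[13]))
    return out


def merge_str_annotations(annotations: Iterable[STRAnnotation]) -> list[STRAnnotation]:
    """Merge overlapping intervals per sequence, keeping input sequence order."""
    per_seq: dict[str, list[STRAnnotation]] = {}
    for ann in annotations:
        per_seq.setdefault(ann.seq_name, []).append(ann)
    merged: list[STRAnnotation] = []
    for seq, anns in per_seq.items():
        anns.sort(key=lambda a: (a.first, a.last))
        current = anns[0]
        for ann in anns[1:]:
            if ann.first <= current.last:
                current = STRAnnotation(
                    seq, current.first, max(current.last, ann.last), current.motif
                )
            else:
                merged.append(current)
                current = ann
        merged.append(current)
    return merged


# ---------------------------------------------------------------------------
# BED intervals (confidence regions)

def read_bed_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Plain BED intervals as (seq, first, last), 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 fields")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for seq, first, last in intervals:
            fh.write(f"{seq}\t{first - 1}\t{last}\n")


def total_interval_length(intervals: Iterable[tuple[str, int, int]]) -> int:
    return sum(last - first + 1 for _, first, last in intervals)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(
    records: Iterable[VariantRecord],
    samples: list[str],
    path: str | os.PathLike,
    contigs: dict[str, int] | ReferenceGenome | None = None,
    command_line: str | None = None,
) -> None:
    """Write coordinate-sorted records as VCF 4.2 with GT:GQ:DP:AD."""
    if isinstance(contigs, ReferenceGenome):
        contigs = {n: len(s) for n, s in contigs.sequences.items()}
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=PASS,Description="All filters passed">')
    if command_line:
        header.add_line(f"##strcall_command={command_line}")
    for name, length in (contigs or {}).items():
        header.contigs.add(name, length=length)
    header.add_line('##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant category: SNV, indel or STR">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth used for the call">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read counts">')
    for sample in samples:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for record in records:
            if record.seq_name not in header.contigs:
                header.contigs.add(record.seq_name)
            out = vf.new_record(
                contig=record.seq_name,
                start=record.position - 1,
                alleles=tuple(record.alleles) if record.alt_alleles else (record.ref_allele, "."),
            )
            out.info["TYPE"] = record.variant_type
            # htslib counts a "." ALT as one allele for Number=R fields
            n_alleles = max(2, 1 + len(record.alt_alleles))
            for sample in samples:
                call = record.call(sample)
                fmt = out.samples[sample]
                if call.is_missing:
                    fmt["GT"] = (None, None)
                else:
                    fmt["GT"] = call.allele_pair
                    fmt.phased = call.phased
                    fmt["GQ"] = min(int(call.gq), 255)
                fmt["DP"] = call.depth
                ad = list(call.allele_depths) if call.allele_depths else [0] * n_alleles
                ad += [0] * (n_alleles - len(ad))
                fmt["AD"] = ad[:n_alleles]
            vf.write(out)


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF back into VariantRecords; returns (records, sample names)."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        lineno = 0
        try:
            for rec in vf:
                lineno += 1
                records.append(_from_pysam_variant(rec, samples))
        except (ValueError, KeyError, TypeError, OSError) as exc:
            raise FormatError(
                f"{path}: malformed VCF record #{lineno + 1}: {exc}"
            ) from exc
    return records, samples


def _from_pysam_variant(rec, samples: list[str]) -> VariantRecord:
    alts = [a for a in (rec.alts or []) if a not in (None, ".", "*", "<NON_REF>")]
    vtype = rec.info.get("TYPE")
    if vtype is None:
        from .core import classify_variant_type

        vtype = classify_variant_type(rec.ref, alts)
    calls: dict[str, GenotypeCall] = {}
    for sample in samples:
        fmt = rec.samples[sample]
        gt = fmt.get("GT")
        if gt is None or any(a is None for a in gt):
            calls[sample] = GenotypeCall(None, depth=int(fmt.get("DP") or 0))
            continue
        pair = (gt[0], gt[-1]) if len(gt) >= 2 else (gt[0], gt[0])
        gq = fmt.get("GQ")
        ad = fmt.get("AD")
        calls[sample] = GenotypeCall(
            allele_pair=pair,
            gq=int(gq) if gq is not None else 0,
            depth=int(fmt.get("DP") or 0),
            allele_depths=tuple(int(x) for x in ad if x is not None) if ad else (),
            phased=bool(fmt.phased),
        )
    return VariantRecord(
        seq_name=rec.chrom,
        position=rec.pos,
        ref_allele=rec.ref.upper(),
        alt_alleles=[a.upper() for a in alts],
        variant_type=str(vtype),
        calls=calls,
    )
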