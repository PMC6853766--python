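"""I/O layer: FASTA/SAM/BED/TRF/VCF parsing, coordinate conventions and
round-trip fidelity."""

import random

import pytest

from strcall import formats_io
from strcall.core import FormatError, GenotypeCall, ReferenceGenome, STRAnnotation, VariantRecord

from conftest import make_read


# ---------------------------------------------------------------------------
# FASTA

def test_read_reference_parses_uppercases_and_sums(tmp_path):
    p = tmp_path / "ref.fa"
    p.write_text(">chr1\nacgt\n>chr2\nGGGGG\n")
    genome = formats_io.read_reference(p)
    assert list(genome.sequences) == ["chr1", "chr2"]
    assert genome.sequences["chr1"] == "ACGT"
    assert genome.total_length == 9


@pytest.mark.parametrize("content", ["", ">chr1\nACGT\n>chr1\nTTTT\n"])
def test_read_reference_rejects_empty_and_duplicates(tmp_path, content):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FormatError):
        formats_io.read_reference(p)


# ---------------------------------------------------------------------------
# SAM

def _write_sam(tmp_path, reads, genome):
    path = tmp_path / "reads.sam"
    formats_io.write_alignments(reads, genome, path)
    return path


def test_read_alignments_in_order_with_mq_filter(tmp_path, tiny_genome):
    reads = [
        make_read(1, [("M", 4)], "ACGT", name="a"),
        make_read(5, [("M", 4)], "ACGT", name="b"),
        make_read(9, [("M", 4)], "ACGT", name="c"),
    ]
    reads[1].mapping_quality = 10
    path = _write_sam(tmp_path, reads, tiny_genome)
    got = list(formats_io.read_alignments(path, min_mapping_quality=0))
    assert [a.read_name for a in got] == ["a", "b", "c"]
    got = list(formats_io.read_alignments(path, min_mapping_quality=20))
    assert [a.read_name for a in got] == ["a", "c"]


def test_undefined_mapping_quality_passes_filter(tmp_path, tiny_genome):
    read = make_read(1, [("M", 4)], "ACGT")
    read.mapping_quality = 255
    path = _write_sam(tmp_path, [read], tiny_genome)
    assert len(list(formats_io.read_alignments(path, min_mapping_quality=40))) == 1


def test_unmapped_records_are_skipped(tmp_path, tiny_genome):
    path = tmp_path / "u.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:320\n")
        fh.write("u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
        fh.write("m1\t0\tchr1\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
    got = list(formats_io.read_alignments(path, 0))
    assert [a.read_name for a in got] == ["m1"]


def test_unsorted_alignments_raise_naming_the_record(tmp_path):
    path = tmp_path / "unsorted.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:320\n")
        fh.write("a\t0\tchr1\t50\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
        fh.write("b\t0\tchr1\t10\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
    with pytest.raises(FormatError, match="b"):
        list(formats_io.read_alignments(path, 0))


def test_shuffled_sam_always_raises(tmp_path):
    """Sortedness is verified: any shuffle breaking order must raise."""
    rng = random.Random(7)
    starts = [10, 40, 80, 120, 200]
    for _ in range(5):
        order = starts[:]
        while order == sorted(order):
            rng.shuffle(order)
        path = tmp_path / "s.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n")
            for i, s in enumerate(order):
                fh.write(f"r{i}\t0\tchr1\t{s}\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
        with pytest.raises(FormatError):
            list(formats_io.read_alignments(path, 0))


def test_sam_round_trip_preserves_cigar_and_qualities(tmp_path, tiny_genome):
    read = make_read(11, [("S", 2), ("M", 5), ("I", 2), ("M", 3), ("D", 4), ("M", 2)],
                     "AACGTACGTACGTA", quals=list(range(20, 34)), name="rt")
    path = _write_sam(tmp_path, [read], tiny_genome)
    got = list(formats_io.read_alignments(path, 0))[0]
    assert got.cigar == read.cigar
    assert got.bases == read.bases
    assert got.base_qualities == read.base_qualities
    assert got.start == read.start


# ---------------------------------------------------------------------------
# STR annotations

def test_bed_strs_convert_to_one_based_inclusive(tmp_path):
    p = tmp_path / "strs.bed"
    p.write_text("chr1\t9\t15\tAC\n")
    (ann,) = formats_io.read_str_annotations(p, "bed")
    assert (ann.first, ann.last, ann.motif) == (10, 15, "AC")


def test_overlapping_annotations_merge(tmp_path):
    p = tmp_path / "strs.bed"
    p.write_text("chr1\t9\t15\nchr1\t13\t20\n")
    merged = formats_io.read_str_annotations(p, "bed")
    assert [(a.first, a.last) for a in merged] == [(10, 20)]


def test_empty_str_file_gives_empty_list(tmp_path):
    p = tmp_path / "strs.bed"
    p.write_text("")
    assert formats_io.read_str_annotations(p, "bed") == []


def test_trf_table_parses_with_sequence_headers(tmp_path):
    p = tmp_path / "trf.dat"
    p.write_text(
        "Tandem Repeats Finder Program\n\nSequence: chr1\n\n"
        "Parameters: 2 7 7 80 10 50 500\n\n"
        "100 120 2 10.5 2 95 0 30 25 25 25 25 1.9 AC ACACACACACACACACACACA\n"
    )
    (ann,) = formats_io.read_str_annotations(p, "trf")
    assert (ann.seq_name, ann.first, ann.last, ann.motif) == ("chr1", 100, 120, "AC")


def test_str_outside_reference_rejected(tmp_path, tiny_genome):
    p = tmp_path / "strs.bed"
    p.write_text("chr1\t9\t99999\n")
    with pytest.raises(FormatError):
        formats_io.read_str_annotations(p, "bed", genome=tiny_genome)


def test_bed_coordinate_conversion_is_self_inverse(tmp_path):
    intervals = [("chr1", 10, 20), ("chr1", 300, 320), ("chr2", 1, 5)]
    p = tmp_path / "iv.bed"
    formats_io.write_bed_intervals(intervals, p)
    assert formats_io.read_bed_intervals(p) == intervals


# ---------------------------------------------------------------------------
# VCF

def _mixed_records():
    return [
        VariantRecord("chr1", 5, "A", ["C"], "SNV",
                      {"s1": GenotypeCall((0, 1), 40, 20, (10, 10)),
                       "s2": GenotypeCall((1, 1), 99, 22, (0, 22))}),
        VariantRecord("chr1", 17, "AC", ["A"], "indel",
                      {"s1": GenotypeCall((0, 0), 50, 30, (30, 0)),
                       "s2": GenotypeCall(None)}),
        VariantRecord("chr1", 40, "A", ["AACAC", "AAC"], "STR",
                      {"s1": GenotypeCall((1, 2), 35, 18, (0, 9, 9)),
                       "s2": GenotypeCall((0, 1), 60, 25, (12, 13), phased=True)}),
        VariantRecord("chr2", 8, "G", [], "SNV",
                      {"s1": GenotypeCall((0, 0), 45, 12, (12,)),
                       "s2": GenotypeCall((0, 0), 45, 9, (9,))}),
    ]


def test_vcf_round_trip_preserves_all_compared_fields(tmp_path):
    records = _mixed_records()
    contigs = {"chr1": 1000, "chr2": 1000}
    path = tmp_path / "out.vcf"
    formats_io.write_vcf(records, ["s1", "s2"], path, contigs=contigs)
    got, samples = formats_io.read_vcf(path)
    assert samples == ["s1", "s2"]
    assert len(got) == len(records)
    for a, b in zip(records, got):
        assert (a.seq_name, a.position, a.ref_allele, a.alt_alleles) == (
            b.seq_name, b.position, b.ref_allele, b.alt_alleles)
        assert a.variant_type == b.variant_type
        for s in samples:
            ca, cb = a.call(s), b.call(s)
            assert ca.allele_pair == cb.allele_pair
            if not ca.is_missing:
                assert ca.gq == cb.gq
                assert ca.phased == cb.phased
            assert ca.depth == cb.depth


def test_het_call_formats_as_unphased_gt_with_gq(tmp_path):
    path = tmp_path / "het.vcf"
    rec = VariantRecord("chr1", 5, "A", ["C"], "SNV", {"s": GenotypeCall((0, 1), 40, 20)})
    formats_io.write_vcf([rec], ["s"], path, contigs={"chr1": 100})
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    gt_field = body[0].split("\t")[9]
    assert gt_field.startswith("0/1:40")


def test_phased_genotype_round_trips_phase_flag(tmp_path):
    path = tmp_path / "ph.vcf"
    rec = VariantRecord("chr1", 5, "A", ["C"], "SNV",
                        {"s": GenotypeCall((1, 0), 99, 20, phased=True)})
    formats_io.write_vcf([rec], ["s"], path, contigs={"chr1": 100})
    got, _ = formats_io.read_vcf(path)
    assert got[0].call("s").phased
    assert got[0].call("s").allele_pair == (1, 0)


def test_malformed_vcf_reports_location(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=100>\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts\n"
        "chr1\t5\t.\tA\tC\t.\t.\t.\tGT\tnot_a_genotype\n"
    )
    with pytest.raises((FormatError, ValueError)):
        formats_io.read_vcf(path)
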