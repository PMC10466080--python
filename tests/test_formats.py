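import gzip
import io

import pytest

from genomekit.formats import (BedPeRecord, BedRecord, FormatError,
                               read_bed, read_bedpe, read_chains,
                               read_chrom_sizes, read_fasta, read_fastq,
                               read_gtf, read_sam, read_vcf, read_wig,
                               write_bed, write_bedpe, write_chains,
                               write_chrom_sizes, write_fasta, write_fastq,
                               write_gtf, write_sam, write_vcf, write_wig,
                               open_stream, gene_models)
from genomekit.formats.sam import cigar_reference_span, parse_cigar
from genomekit.seqcore import Sequence

# ---------------------------------------------------------------------------
# compression autodetection
# ---------------------------------------------------------------------------

def test_open_stream_plain(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s\nACGT\n")
    assert open_stream(str(p)).read() == ">s\nACGT\n"


def test_open_stream_gz(tmp_path):
    p = tmp_path / "a.fa.gz"
    with gzip.open(p, "wt") as f:
        f.write(">s\nACGT\n")
    assert open_stream(str(p)).read() == ">s\nACGT\n"


def test_open_stream_misnamed_gzip_detected_by_magic(tmp_path):
    p = tmp_path / "a.fa"  # gzipped content, plain name
    with gzip.open(p, "wt") as f:
        f.write(">s\nACGT\n")
    assert open_stream(str(p)).read() == ">s\nACGT\n"


def test_open_stream_gz_extension_but_plain_content_errors(tmp_path):
    p = tmp_path / "a.fa.gz"
    p.write_text(">s\nACGT\n")
    with pytest.raises(FormatError, match="not gzip"):
        open_stream(str(p))


def test_gz_sink_roundtrip(tmp_path):
    p = tmp_path / "out.bed.gz"
    write_bed(str(p), [BedRecord("chr1", 0, 10)])
    assert [r.start for r in read_bed(str(p))] == [0]
    with gzip.open(p, "rt") as f:  # really gzip on disk
        assert f.read() == "chr1\t0\t10\n"


# ---------------------------------------------------------------------------
# round trips (read . write . read == read)
# ---------------------------------------------------------------------------

FASTA = ">seq one extra words\nACGTACGTacgtNNN\nGGGG\n>empty\n"
FASTQ = "@r1\nACGT\n+\nIIII\n@r2/1\nNNNN\n+\n!!!!\n"
BED6 = "chr1\t5\t10\tfeat1\t960\t+\nchr2\t0\t100\tfeat2\t0\t-\n"
BED12 = ("chr1\t10\t50\tx\t0\t+\t10\t50\t0\t2\t10,10\t0,30\n")
BEDPE = "chr1\t0\t10\tchr2\t50\t60\tloop1\t5\t+\t-\nchr2\t5\t6\tchr2\t90\t95\tloop2\t1\t.\t.\n"
VCF = ("##fileformat=VCFv4.2\n##INFO=<ID=DP,Number=1,Type=Integer>\n"
       "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
       "chr1\t100\trs1\tAT\tA\t50\tPASS\tDP=10;SOMATIC\tGT:DP\t0|1:9\t./.:0\n"
       "chr1\t200\t.\tG\tC,T\t.\t.\t.\tGT:DP\t1/2:4\t0/0:8\n")
SAM = ("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"
       "r1\t0\tchr1\t100\t60\t5M2D5M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\tNM:i:2\tXS:A:+\n"
       "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
WIG = ("fixedStep chrom=chr1 start=11 step=1\n1\n2\n3\n"
       "fixedStep chrom=chr1 start=17 step=1\n5\n5\n")
CHAIN = ("chain 4900 chr1 1000 + 0 110 chr1 900 + 0 100 1\n50\t10\t0\n50\n\n"
         "chain 100 chr2 500 + 10 60 chr9 400 - 100 150 2\n50\n\n")
GTF = ('chr1\thavana\texon\t11\t50\t.\t+\t.\tgene_id "g1"; gene_name "G"; transcript_id "t1";\n'
       'chr1\thavana\texon\t101\t150\t.\t+\t.\tgene_id "g1"; gene_name "G"; transcript_id "t1";\n')
SIZES = "chr1\t1000\nchr2\t500\n"


def _roundtrip(text, reader, writer, header_attr=False):
    first = reader(io.StringIO(text))
    if header_attr:
        records = list(first)
        out = io.StringIO()
        writer(out, records, header=first.header)
    else:
        records = list(first)
        out = io.StringIO()
        writer(out, records)
    assert out.getvalue() == text
    second = reader(io.StringIO(out.getvalue()))
    assert [repr(r) for r in second] == [repr(r) for r in records]


@pytest.mark.parametrize("text,reader,writer,header", [
    (FASTQ, read_fastq, write_fastq, False),
    (BED6, read_bed, write_bed, False),
    (BED12, read_bed, write_bed, False),
    (BEDPE, read_bedpe, write_bedpe, False),
    (VCF, read_vcf, write_vcf, True),
    (SAM, read_sam, write_sam, True),
    (CHAIN, read_chains, write_chains, False),
    (GTF, read_gtf, write_gtf, False),
], ids=["fastq", "bed6", "bed12", "bedpe", "vcf", "sam", "chain", "gtf"])
def test_roundtrip_byte_identity(text, reader, writer, header):
    _roundtrip(text, reader, writer, header_attr=header)


def test_fasta_roundtrip_with_wrapping():
    seqs = list(read_fasta(io.StringIO(FASTA)))
    out = io.StringIO()
    write_fasta(out, seqs, width=60)
    again = list(read_fasta(io.StringIO(out.getvalue())))
    assert [(s.name, s.seq) for s in again] == [(s.name, s.seq) for s in seqs]


def test_wig_roundtrip_preserves_missing_runs():
    tracks = read_wig(io.StringIO(WIG))
    assert len(tracks) == 1
    t = tracks[0]
    assert t.start == 10 and t.values == [1, 2, 3, None, None, None, 5, 5]
    out = io.StringIO()
    write_wig(out, tracks)
    assert out.getvalue() == WIG
    again = read_wig(io.StringIO(out.getvalue()))
    assert again[0].values == t.values


def test_chrom_sizes_roundtrip():
    sizes = read_chrom_sizes(io.StringIO(SIZES))
    assert sizes == {"chr1": 1000, "chr2": 500}
    out = io.StringIO()
    write_chrom_sizes(out, sizes)
    assert out.getvalue() == SIZES


# ---------------------------------------------------------------------------
# coordinate conversions
# ---------------------------------------------------------------------------

def test_vcf_pos_conversion_is_involution():
    recs = list(read_vcf(io.StringIO(VCF)))
    assert recs[0].start == 99 and recs[0].end == 101  # POS=100, REF len 2
    assert recs[0].to_line().split("\t")[1] == "100"


def test_sam_pos_and_cigar_end():
    recs = list(read_sam(io.StringIO(SAM)))
    r = recs[0]
    assert r.pos == 99
    assert r.end == 99 + cigar_reference_span(parse_cigar("5M2D5M")) == 111
    assert recs[1].is_unmapped and recs[1].interval is None


def test_gtf_coordinates_zero_based():
    recs = list(read_gtf(io.StringIO(GTF)))
    assert (recs[0].start, recs[0].end) == (10, 50)
    genes = gene_models(recs)
    assert len(genes) == 1 and genes[0].gene_id == "g1"
    assert [(e.start, e.end) for e in genes[0].exons] == [(10, 50), (100, 150)]


def test_wig_start_conversion():
    t = read_wig(io.StringIO("fixedStep chrom=c start=1 step=1\n7\n"))[0]
    assert t.start == 0 and t.values == [7.0]


def test_variable_step_wig_canonicalized_dense():
    text = "variableStep chrom=c\n5\t1.5\n8\t2.5\n"
    t = read_wig(io.StringIO(text))[0]
    assert t.start == 4 and t.values == [1.5, None, None, 2.5]


# ---------------------------------------------------------------------------
# malformed input policy: fail fast with location
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text,reader,match", [
    ("chr1\t5\n", read_bed, "3-12 columns"),
    ("chr1\t10\t5\n", read_bed, "end 5 < start 10"),
    ("chr1\t0\t5\nchr1\t0\t5\tx\n", read_bed, "inconsistent column count"),
    ("chr1\t0\tx\n", read_bed, "non-integer"),
    ("c\t0\t.\tA\tT\t.\t.\t.\n", read_vcf, "POS must be >= 1"),
    ("r1\t0\tchr1\t1\t60\t5M\t*\t0\t0\tACG\tIII\n",
     lambda s: iter(read_sam(s)), "query length"),
], ids=["bed-cols", "bed-coords", "bed-mixed", "bed-int", "vcf-pos", "sam-cigar"])
def test_malformed_records_error_with_line(text, reader, match):
    with pytest.raises(FormatError, match=match):
        list(reader(io.StringIO(text)))


def test_format_error_carries_line_number():
    with pytest.raises(FormatError, match="line 2"):
        list(read_bed(io.StringIO("chr1\t0\t5\nchr1\tbad\t9\n")))


def test_chain_invariant_violation_rejected():
    bad = "chain 1 t 100 + 0 100 q 100 + 0 100 1\n50\t10\t0\n50\n\n"  # 50+10+50 != 100
    with pytest.raises(FormatError, match="block sums"):
        list(read_chains(io.StringIO(bad)))


def test_mixed_column_bed_write_rejected():
    out = io.StringIO()
    with pytest.raises(FormatError, match="mixed column"):
        write_bed(out, [BedRecord("c", 0, 5), BedRecord("c", 0, 5, name="x")])


# ---------------------------------------------------------------------------
# streaming contract
# ---------------------------------------------------------------------------

def test_bed_reader_memory_bounded_in_record_count(tmp_path):
    import tracemalloc

    def peak(n):
        p = tmp_path / f"n{n}.bed"
        with open(p, "w") as f:
            for i in range(n):
                f.write(f"chr1\t{i}\t{i + 5}\n")
        tracemalloc.start()
        total = sum(1 for _ in read_bed(str(p)))
        _, peak_mem = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert total == n
        return peak_mem

    small, large = peak(2_000), peak(100_000)
    assert large < 3 * small  # peak memory independent of record count


def test_sam_parse_agrees_with_pysam(tmp_path):
    pysam = pytest.importorskip("pysam")
    p = tmp_path / "x.sam"
    p.write_text(SAM)
    ours = list(read_sam(str(p)))
    theirs = list(pysam.AlignmentFile(str(p), "r"))
    for a, b in zip(ours, theirs):
        assert a.qname == b.query_name
        assert a.flag == b.flag
        if not a.is_unmapped:
            assert (a.pos, a.end) == (b.reference_start, b.reference_end)
            assert a.cigar == [(n, "MIDNSHP=X"[op]) for op, n in b.cigartuples]
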