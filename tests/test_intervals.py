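import io

import numpy as np
import pytest

from genomekit.formats import BedPeRecord, BedRecord, read_bed, write_bed
from genomekit.formats.core import GenomicInterval
from genomekit.intervals import (GenomeOrder, IntervalIndex,
                                 bed_distance_from_chr_ends,
                                 bedpe_filter_overlap, genome_sort,
                                 interval_contacts, query_overlaps)


def _random_beds(rng, n, n_chroms=3, span=10_000, max_len=200):
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    out = []
    for _ in range(n):
        c = chroms[int(rng.integers(n_chroms))]
        s = int(rng.integers(0, span))
        out.append(BedRecord(c, s, s + int(rng.integers(1, max_len))))
    return out


def _brute_force(records, chrom, start, end):
    return [r for r in records
            if r.chrom == chrom and r.start < end and start < r.end]


def test_empty_index_returns_nothing():
    idx = IntervalIndex([])
    assert idx.query("chr1", 0, 100) == []


def test_single_interval_hit_and_boundary():
    r = BedRecord("chr1", 0, 10)
    idx = IntervalIndex([r])
    assert idx.query("chr1", 5, 6) == [r]
    assert idx.query("chr1", 10, 11) == []  # half-open adjacency
    assert idx.query("chr2", 5, 6) == []    # unknown chromosome


def test_query_overlaps_example():
    a, b = BedRecord("chr1", 0, 10), BedRecord("chr1", 5, 15)
    idx = IntervalIndex([a, b])
    assert query_overlaps(idx, GenomicInterval("chr1", 9, 12)) == [a, b]


def test_zero_length_intervals_overlap_nothing():
    idx = IntervalIndex([BedRecord("chr1", 5, 5)])
    assert idx.n_zero_length == 1
    assert idx.query("chr1", 0, 100) == []
    # zero-length queries also hit nothing
    idx2 = IntervalIndex([BedRecord("chr1", 0, 10)])
    assert idx2.query("chr1", 5, 5) == []


def test_unmapped_records_skipped_with_counter():
    from genomekit.formats.sam import parse_sam_line
    unmapped = parse_sam_line("r\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII")
    idx = IntervalIndex([unmapped, BedRecord("chr1", 0, 5)])
    assert idx.n_skipped == 1 and idx.n_records == 1


def test_index_matches_brute_force_on_random_instances(rng):
    records = _random_beds(rng, 10_000)
    idx = IntervalIndex(records)
    for _ in range(500):
        c = f"chr{int(rng.integers(3)) + 1}"
        s = int(rng.integers(0, 10_000))
        e = s + int(rng.integers(1, 400))
        got = idx.query(c, s, e)
        want = _brute_force(records, c, s, e)
        assert sorted(id(r) for r in got) == sorted(id(r) for r in want)


def test_overlap_symmetric(rng):
    for _ in range(200):
        s1, s2 = rng.integers(0, 100, size=2)
        a = GenomicInterval("c", int(s1), int(s1 + rng.integers(1, 30)))
        b = GenomicInterval("c", int(s2), int(s2 + rng.integers(1, 30)))
        assert a.overlaps(b) == b.overlaps(a)


def test_query_independent_of_insertion_order(rng):
    records = _random_beds(rng, 500)
    idx1 = IntervalIndex(records)
    shuffled = list(records)
    rng.shuffle(shuffled)
    idx2 = IntervalIndex(shuffled)
    for _ in range(50):
        s = int(rng.integers(0, 10_000))
        q1 = idx1.query("chr1", s, s + 100)
        q2 = idx2.query("chr1", s, s + 100)
        assert {id(r) for r in q1} == {id(r) for r in q2}


# ---------------------------------------------------------------------------
# external genome sort
# ---------------------------------------------------------------------------

def test_genome_sort_reversed_bed(tmp_path):
    src = tmp_path / "in.bed"
    dst = tmp_path / "out.bed"
    src.write_text("chr1\t30\t40\nchr1\t20\t30\nchr1\t0\t10\n")
    genome_sort(str(src), str(dst), "bed")
    assert dst.read_text() == "chr1\t0\t10\nchr1\t20\t30\nchr1\t30\t40\n"


def test_genome_sort_deterministic_tie_break(tmp_path):
    src = tmp_path / "in.bed"
    dst = tmp_path / "out.bed"
    src.write_text("chr1\t5\t9\tb\nchr1\t5\t9\ta\nchr1\t5\t9\tc\n")
    # same coordinates: total order falls back to the serialized record
    genome_sort(str(src), str(dst), "bed")
    assert dst.read_text() == "chr1\t5\t9\ta\nchr1\t5\t9\tb\nchr1\t5\t9\tc\n"


def test_genome_sort_external_chunks_match_in_memory(tmp_path, rng):
    records = _random_beds(rng, 50_000)
    src, dst = tmp_path / "in.bed", tmp_path / "out.bed"
    write_bed(str(src), records)
    genome_sort(str(src), str(dst), "bed", chunk_size=1_000)
    lines = src.read_text().splitlines()

    def key(line):
        c = line.split("\t")
        return (c[0], int(c[1]), int(c[2]), line)

    assert dst.read_text().splitlines() == sorted(lines, key=key)


def test_genome_sort_idempotent(tmp_path, rng):
    records = _random_beds(rng, 2_000)
    a, b, c = (tmp_path / n for n in ("a.bed", "b.bed", "c.bed"))
    write_bed(str(a), records)
    genome_sort(str(a), str(b), "bed", chunk_size=100)
    genome_sort(str(b), str(c), "bed", chunk_size=100)
    assert b.read_text() == c.read_text()


def test_genome_sort_explicit_order_and_unknown_chrom(tmp_path):
    src, dst = tmp_path / "in.bed", tmp_path / "out.bed"
    src.write_text("chr2\t0\t5\nchr10\t0\t5\n")
    # natural order from chrom.sizes: chr2 before chr10
    genome_sort(str(src), str(dst), "bed", order=GenomeOrder(["chr2", "chr10"]))
    assert dst.read_text().splitlines() == ["chr2\t0\t5", "chr10\t0\t5"]
    with pytest.raises(ValueError, match="chr10"):
        genome_sort(str(src), str(dst), "bed", order=GenomeOrder(["chr2"]))


def test_genome_sort_vcf_keeps_header(tmp_path):
    src, dst = tmp_path / "in.vcf", tmp_path / "out.vcf"
    src.write_text("##x\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                   "c\t20\t.\tA\tT\t.\t.\t.\n"
                   "c\t10\t.\tA\tT\t.\t.\t.\n")
    genome_sort(str(src), str(dst), "vcf")
    lines = dst.read_text().splitlines()
    assert lines[0] == "##x" and lines[2].split("\t")[1] == "10"


def test_barcode_sort(tmp_path):
    src, dst = tmp_path / "in.bed", tmp_path / "out.bed"
    src.write_text("q1_CB:TTT\t0\t5\nq2_CB:AAA\t0\t5\n")
    genome_sort(str(src), str(dst), "bed", by_barcode=True)
    assert dst.read_text().splitlines()[0].startswith("q2_CB:AAA")


# ---------------------------------------------------------------------------
# BEDPE operations
# ---------------------------------------------------------------------------

def _pe(c1, s1, e1, c2, s2, e2):
    return BedPeRecord(c1, s1, e1, c2, s2, e2)


def test_bedpe_either_vs_both_feet_bed_targets():
    rec = _pe("chr1", 0, 10, "chr2", 50, 60)
    target = [BedRecord("chr2", 55, 57)]
    assert list(bedpe_filter_overlap([rec], target, mode="either-foot"))
    assert not list(bedpe_filter_overlap([rec], [BedRecord("chr2", 55, 57)],
                                         mode="both-feet"))


def test_bedpe_both_feet_bedpe_target_requires_single_pairing():
    rec = _pe("chr1", 0, 10, "chr2", 50, 60)
    paired = [_pe("chr2", 55, 57, "chr1", 2, 4)]  # reversed orientation: ok
    split = [_pe("chr1", 2, 4, "chr3", 0, 5), _pe("chr3", 9, 12, "chr2", 55, 57)]
    assert list(bedpe_filter_overlap([rec], paired, mode="both-feet",
                                     target_kind="bedpe"))
    assert not list(bedpe_filter_overlap([rec], split, mode="both-feet",
                                         target_kind="bedpe"))


def test_bedpe_both_feet_matches_quadratic_oracle(rng):
    def rand_pe(n):
        out = []
        for _ in range(n):
            c1, c2 = (f"chr{int(rng.integers(2)) + 1}" for _ in range(2))
            s1, s2 = (int(rng.integers(0, 1000)) for _ in range(2))
            out.append(_pe(c1, s1, s1 + int(rng.integers(1, 50)),
                           c2, s2, s2 + int(rng.integers(1, 50))))
        return out

    query, targets = rand_pe(100), rand_pe(60)

    def ov(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    expected = [
        q for q in query
        if any((ov(q.foot_a, t.foot_a) and ov(q.foot_b, t.foot_b))
               or (ov(q.foot_a, t.foot_b) and ov(q.foot_b, t.foot_a))
               for t in targets)
    ]
    got = list(bedpe_filter_overlap(query, targets, mode="both-feet",
                                    target_kind="bedpe"))
    assert got == expected


def test_interval_contacts(rng):
    feet = [_pe("chr1", 100, 200, "chr2", 50, 60)]
    kept = list(interval_contacts(feet, [BedRecord("chr2", 55, 57),
                                         BedRecord("chr3", 55, 57)]))
    assert [(r.chrom, r.start) for r in kept] == [("chr2", 55)]
    # random agreement with brute force
    bedpe = [
        _pe("chr1", int(s1), int(s1) + 20, "chr2", int(s2), int(s2) + 20)
        for s1, s2 in rng.integers(0, 1000, size=(40, 2))
    ]
    queries = [BedRecord(f"chr{int(rng.integers(2)) + 1}", int(s), int(s) + 10)
               for s in rng.integers(0, 1000, size=200)]

    def ov(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    expected = [q for q in queries
                if any(ov(q.interval, t.foot_a) or ov(q.interval, t.foot_b)
                       for t in bedpe)]
    assert list(interval_contacts(bedpe, queries)) == expected


# ---------------------------------------------------------------------------
# distances from chromosome ends
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("start,end,expected", [
    (10, 20, 10),
    (95, 100, 0),
    (40, 50, 40),  # min(start, size - end) = min(40, 50)
])
def test_bed_distance_from_chr_ends(start, end, expected):
    (out,) = bed_distance_from_chr_ends([BedRecord("c", start, end)], {"c": 100})
    assert out.score == str(expected)


def test_bed_distance_rejects_record_past_end():
    with pytest.raises(ValueError, match="past chromosome end"):
        list(bed_distance_from_chr_ends([BedRecord("c", 90, 110)], {"c": 100}))
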