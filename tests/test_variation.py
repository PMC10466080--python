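import math

import numpy as np
import pytest

from genomekit import variation as var
from genomekit.formats.core import GenomicInterval
from genomekit.formats.sam import parse_sam_line
from genomekit.formats.vcf import parse_vcf_line
from genomekit.seqcore import Sequence
from genomekit.variation.pileup import PileupColumn


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def _sam(line):
    return parse_sam_line(line)


def test_pileup_simple_match_columns():
    ref = {"c": Sequence("c", "A" * 30)}
    r = _sam("r\t0\tc\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII")
    cols = list(var.pileup([r], ref))
    assert [c.pos for c in cols] == list(range(10))
    assert all(c.counts["A"] == 1 and c.ref_base == "A" for c in cols)


def test_pileup_deletion_columns():
    ref = {"c": Sequence("c", "A" * 30)}
    r = _sam("r\t0\tc\t1\t60\t5M2D5M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII")
    cols = {c.pos: c for c in var.pileup([r], ref)}
    assert cols[5].counts["DEL"] == 1 and cols[6].counts["DEL"] == 1
    assert cols[5].counts["A"] == 0
    assert cols[7].counts["A"] == 1  # match resumes after the deletion


def test_pileup_insertion_anchor_and_splice_skip():
    ref = {"c": Sequence("c", "A" * 50)}
    r = _sam("r\t0\tc\t1\t60\t5M2I3M10N2M\t*\t0\t0\tAAAAAAAAAAAA\tIIIIIIIIIIII")
    cols = {c.pos: c for c in var.pileup([r], ref)}
    assert cols[4].counts["INS"] == 1  # anchored at the base to the left
    assert 8 not in cols or cols[8].counts["A"] == 0  # N region uncovered
    assert cols[18].counts["A"] == 1  # resumes after the splice gap


def test_pileup_quality_filters():
    ref = {"c": Sequence("c", "A" * 10)}
    low_bq = _sam("r\t0\tc\t1\t60\t4M\t*\t0\t0\tAAAA\t!!!!")  # Q0 bases
    cols = list(var.pileup([low_bq], ref, min_base_qual=20))
    assert all(c.counts["A"] == 0 for c in cols)
    low_mq = _sam("r\t0\tc\t1\t5\t4M\t*\t0\t0\tAAAA\tIIII")
    assert list(var.pileup([low_mq], ref, min_map_qual=20)) == []


def test_pileup_rejects_unsorted():
    ref = {"c": Sequence("c", "A" * 50)}
    a = _sam("a\t0\tc\t20\t60\t4M\t*\t0\t0\tAAAA\tIIII")
    b = _sam("b\t0\tc\t1\t60\t4M\t*\t0\t0\tAAAA\tIIII")
    with pytest.raises(ValueError, match="not sorted"):
        list(var.pileup([a, b], ref))


def test_pileup_error_rate_recovered(tiny_genome):
    from genomekit.simulate import ReadSimConfig, simulate_sam
    eps = 0.02
    cfg = ReadSimConfig(n_reads=400, read_length=80, error_rate=eps, seed=6)
    records, _ = simulate_sam(tiny_genome, cfg)
    records.sort(key=lambda r: (r.rname, r.pos))
    mismatch = total = 0
    for col in var.pileup(records, tiny_genome, min_base_qual=0):
        d = col.depth
        mismatch += d - col.counts[col.ref_base]
        total += d
    sd = math.sqrt(eps * (1 - eps) / total)
    assert abs(mismatch / total - eps) < 3 * sd


# ---------------------------------------------------------------------------
# somatic calling
# ---------------------------------------------------------------------------

def _col(pos, ref_base, **counts):
    c = PileupColumn("c", pos, ref_base)
    c.counts.update(counts)
    return c


def test_fisher_p_matches_exhaustive_hypergeometric(rng):
    # every table with both row margins <= 12 (dense exhaustive check);
    # larger margins are sampled in the acceptance suite
    for r1 in range(1, 13):
        for r2 in range(1, 13):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    K, N = a + c, r1 + r2
                    # enumeration oracle: P(X >= a), X ~ Hypergeom(N, K, r1)
                    p = sum(
                        math.comb(K, k) * math.comb(N - K, r1 - k)
                        for k in range(a, min(K, r1) + 1)
                    ) / math.comb(N, r1)
                    assert var.fisher_somatic_p(a, b, c, d) == pytest.approx(
                        p, rel=1e-9)


def test_call_variants_example_table():
    exp = _col(5, "A", A=10, T=10)
    norm = _col(5, "A", A=20)
    calls = list(var.call_variants([exp], [norm], max_p=1e-3))
    p = var.fisher_somatic_p(10, 10, 0, 20)
    assert (len(calls) == 1) == (p <= 1e-3)
    assert calls[0].alts == ("T",)
    assert float(calls[0].info["PVAL"]) == pytest.approx(p, rel=1e-6)


def test_identical_counts_not_called():
    exp = _col(1, "A", A=10, T=5)
    norm = _col(1, "A", A=10, T=5)
    assert not list(var.call_variants([exp], [norm], max_normal_af=1.0))


def test_min_alt_reads_threshold():
    stats = var.CallStats()
    exp = _col(1, "A", A=20, T=1)
    norm = _col(1, "A", A=20)
    list(var.call_variants([exp], [norm], min_alt_reads=2, stats_out=stats))
    assert stats.tested == 0


def test_missing_normal_column_skipped():
    stats = var.CallStats()
    exp = _col(1, "A", A=5, T=5)
    assert not list(var.call_variants([exp], [], stats_out=stats))
    assert stats.no_normal == 1


# ---------------------------------------------------------------------------
# allele frequency spectra
# ---------------------------------------------------------------------------

def _vcf(line):
    return parse_vcf_line(line)


def test_afs_derived_count_three():
    recs = [_vcf("c\t1\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1")]
    afs = var.compute_afs(recs)
    assert afs.n_chromosomes == 4 and afs[3] == 1 and afs.total == 1


def test_afs_skips_non_segregating_and_missing():
    recs = [_vcf("c\t1\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/0"),
            _vcf("c\t2\t.\tA\tT\t.\t.\t.\tGT\t0/1\t./."),
            _vcf("c\t3\t.\tA\tT\t.\t.\t.\tGT\t0/1\t0/0")]
    afs = var.compute_afs(recs)
    assert afs.total == 1 and afs.n_skipped == 2


def test_afs_requires_usable_records():
    with pytest.raises(ValueError, match="no usable"):
        var.compute_afs([_vcf("c\t1\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/0")])


def test_afs_folding():
    recs = [_vcf("c\t1\t.\tA\tT\t.\t.\t.\tGT\t1/1\t1/0"),  # derived 3
            _vcf("c\t2\t.\tA\tT\t.\t.\t.\tGT\t0/1\t0/0")]  # derived 1
    folded = var.compute_afs(recs, polarized=False)
    assert folded.folded and folded[1] == 2


def test_simulate_vcf_roundtrip_matches_truth_tally():
    records, truth = var.simulate_vcf(500, 6, alpha=-3.0, seed=9)
    afs = var.compute_afs(records)
    assert np.array_equal(afs.counts, truth.counts)
    assert afs.total == 500  # conservation


def test_simulate_vcf_deterministic():
    a, _ = var.simulate_vcf(50, 4, 1.0, seed=3)
    b, _ = var.simulate_vcf(50, 4, 1.0, seed=3)
    assert [r.to_line() for r in a] == [r.to_line() for r in b]


def test_negative_selection_inflates_singletons():
    rng_a = np.random.default_rng(1)
    rng_b = np.random.default_rng(1)
    neutral = var.sample_derived_counts(20_000, 20, 0.0, rng_a)
    selected = var.sample_derived_counts(20_000, 20, -20.0, rng_b)
    assert (selected == 1).mean() > (neutral == 1).mean()


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def test_haplotypes_basic_substitution():
    ref = {"c": Sequence("c", "AAAA")}
    rec = _vcf("c\t2\t.\tA\tC\t.\t.\t.\tGT\t1|0")
    haps = var.haplotype_generator([rec], ref, GenomicInterval("c", 0, 4))
    assert {(s.seq, n) for s, n in haps} == {("ACAA", 1), ("AAAA", 1)}


def test_haplotypes_no_variants_single_haplotype():
    ref = {"c": Sequence("c", "ACGTACGT")}
    rec = _vcf("c\t100\t.\tA\tC\t.\t.\t.\tGT\t1|0\t0|0\t1|1")  # outside region
    haps = var.haplotype_generator([rec], ref, GenomicInterval("c", 0, 8))
    assert len(haps) == 1
    seq, count = haps[0]
    assert seq.seq == "ACGTACGT" and count == 6


def test_haplotypes_unphased_rejected_unless_flagged():
    ref = {"c": Sequence("c", "AAAA")}
    rec = _vcf("c\t2\t.\tA\tC\t.\t.\t.\tGT\t0/1")
    with pytest.raises(ValueError, match="unphased"):
        var.haplotype_generator([rec], ref, GenomicInterval("c", 0, 4))
    haps = var.haplotype_generator([rec], ref, GenomicInterval("c", 0, 4),
                                   assume_phased=True)
    assert sum(n for _, n in haps) == 2


def test_haplotypes_match_string_edit_oracle(rng):
    ref_seq = "".join(rng.choice(list("ACGT"), size=60))
    ref = {"c": Sequence("c", ref_seq)}
    positions = sorted(rng.choice(np.arange(5, 55), size=3, replace=False))
    records, alleles = [], []
    for p in positions:
        alt = "ACGT"[(("ACGT".index(ref_seq[p])) + 1) % 4]
        gts = [f"{rng.integers(2)}|{rng.integers(2)}" for _ in range(5)]
        records.append(_vcf(
            f"c\t{p + 1}\t.\t{ref_seq[p]}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)))
        alleles.append((p, alt, [int(x) for gt in gts for x in gt.split("|")]))
    haps = var.haplotype_generator(records, ref, GenomicInterval("c", 0, 60))
    # oracle: per-haplotype character substitution
    expected: dict[str, int] = {}
    for h in range(10):
        chars = list(ref_seq)
        for p, alt, hap_alleles in alleles:
            if hap_alleles[h]:
                chars[p] = alt
        s = "".join(chars)
        expected[s] = expected.get(s, 0) + 1
    assert {(s.seq, n) for s, n in haps} == set(expected.items())


def test_haplotypes_indel_right_to_left():
    ref = {"c": Sequence("c", "AACCGG")}
    recs = [_vcf("c\t2\t.\tAC\tA\t.\t.\t.\tGT\t1|0"),   # deletion of C at pos 3
            _vcf("c\t5\t.\tG\tGTT\t.\t.\t.\tGT\t1|1")]  # insertion after G
    haps = var.haplotype_generator(recs, ref, GenomicInterval("c", 0, 6))
    assert {(s.seq, n) for s, n in haps} == {("AACGTTG", 1), ("AACCGTTG", 1)}


# ---------------------------------------------------------------------------
# multiple alignment to VCF
# ---------------------------------------------------------------------------

def test_msa_single_snv():
    aln = [Sequence("ref", "ACGT"), Sequence("s1", "ACCT")]
    records, gaps = var.multi_fa_to_vcf(aln, "ref")
    assert gaps == 0 and len(records) == 1
    r = records[0]
    assert (r.start + 1, r.ref, r.alts) == (3, "G", ("C",))


def test_msa_gap_column_skipped_and_counted():
    aln = [Sequence("ref", "AC-GT"), Sequence("s1", "ACTGT")]
    records, gaps = var.multi_fa_to_vcf(aln, "ref")
    assert records == [] and gaps == 1


def test_msa_matches_column_oracle(rng):
    cols = 40
    seqs = []
    for name in ("ref", "s1", "s2"):
        seqs.append(Sequence(name, "".join(rng.choice(list("ACGT-"),
                                                      size=cols,
                                                      p=[.23, .23, .23, .23, .08]))))
    records, gaps = var.multi_fa_to_vcf(seqs, "ref")
    by_pos = {r.start: r for r in records}
    ref_pos = 0
    oracle_gaps = 0
    for i in range(cols):
        col = [s.seq[i] for s in seqs]
        if "-" in col:
            oracle_gaps += 1
            if col[0] != "-":
                ref_pos += 1
            continue
        alts = sorted({b for b in col[1:] if b != col[0]})
        if alts:
            assert by_pos[ref_pos].alts == tuple(alts)
        else:
            assert ref_pos not in by_pos
        ref_pos += 1
    assert gaps == oracle_gaps


def test_msa_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        var.multi_fa_to_vcf([Sequence("ref", "ACG"), Sequence("s", "AC")], "ref")
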