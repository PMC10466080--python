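"""CIGAR-aware pileup and tumor/normal somatic variant calling.

Pileup columns tally A/C/G/T plus insertion and deletion events per
reference position after base- and mapping-quality filters, counting only
primary mapped alignments.  Somatic calls compare an experimental against
a normal (matched control) pileup with a one-sided Fisher's exact test on
the 2x2 table of alt/ref read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from scipy import stats

from ..formats.sam import SamRecord
from ..formats.vcf import VcfRecord
from ..seqcore import Sequence

BASES = ("A", "C", "G", "T")
INS = "INS"
DEL = "DEL"


@dataclass
class PileupColumn:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(
        (*BASES, INS, DEL), 0))

    @property
    def depth(self) -> int:
        """Base-call depth (A+C+G+T)."""
        return sum(self.counts[b] for b in BASES)

    def allele_fraction(self, allele: str) -> float:
        d = self.depth
        return self.counts[allele] / d if d else 0.0


def pileup(sam_records: Iterable[SamRecord], ref: dict[str, Sequence],
           min_base_qual: int = 20, min_map_qual: int = 20) -> Iterator[PileupColumn]:
    """Stream pileup columns in genome order from sorted SAM records.

    CIGAR semantics: M/=/X consume reference and query and contribute base
    calls; I is counted as an insertion anchored at the base to its left;
    D contributes a deletion count at every spanned column; N skips the
    reference; S skips the query; H and P consume nothing.  Input must be
    coordinate-sorted (checked) and only primary mapped alignments with
    sufficient mapping quality are counted.
    """
    active: dict[int, PileupColumn] = {}
    cur_chrom: str | None = None
    last_start = -1
    seen_chroms: set[str] = set()

    def flush(upto: int | None) -> Iterator[PileupColumn]:
        for p in sorted(active):
            if upto is not None and p >= upto:
                break
            yield active.pop(p)

    def column(chrom: str, pos: int) -> PileupColumn:
        col = active.get(pos)
        if col is None:
            base = ref[chrom].seq[pos].upper() if chrom in ref else "N"
            col = active[pos] = PileupColumn(chrom, pos, base)
        return col

    for rec in sam_records:
        if rec.is_unmapped or not rec.is_primary or rec.cigar is None:
            continue
        if rec.mapq < min_map_qual:
            continue
        if rec.rname != cur_chrom:
            if rec.rname in seen_chroms:
                raise ValueError(f"input not sorted: {rec.rname} appears twice")
            yield from flush(None)
            cur_chrom = rec.rname
            seen_chroms.add(cur_chrom)
            last_start = -1
        if rec.pos < last_start:
            raise ValueError(
                f"input not sorted: {rec.rname}:{rec.pos + 1} after {last_start + 1}"
            )
        last_start = rec.pos
        yield from flush(rec.pos)

        ref_pos = rec.pos
        query_pos = 0
        for length, op in rec.cigar:
            if op in "M=X":
                for k in range(length):
                    b = rec.seq[query_pos + k].upper()
                    if rec.qual != "*":
                        if ord(rec.qual[query_pos + k]) - 33 < min_base_qual:
                            continue
                    if b in BASES:
                        column(rec.rname, ref_pos + k).counts[b] += 1
                ref_pos += length
                query_pos += length
            elif op == "I":
                anchor = ref_pos - 1 if ref_pos > rec.pos else ref_pos
                column(rec.rname, anchor).counts[INS] += 1
                query_pos += length
            elif op == "D":
                for k in range(length):
                    column(rec.rname, ref_pos + k).counts[DEL] += 1
                ref_pos += length
            elif op == "N":
                ref_pos += length
            elif op == "S":
                query_pos += length
            # H, P consume nothing
    yield from flush(None)


def fisher_somatic_p(exp_alt: int, exp_ref: int, norm_alt: int, norm_ref: int) -> float:
    """One-sided Fisher's exact p for alt enrichment in the experimental sample."""
    _, p = stats.fisher_exact([[exp_alt, exp_ref], [norm_alt, norm_ref]],
                              alternative="greater")
    return float(p)


@dataclass
class CallStats:
    tested: int = 0
    called: int = 0
    no_normal: int = 0  # experimental columns without a matched normal column


def call_variants(experimental: Iterable[PileupColumn],
                  normal: Iterable[PileupColumn],
                  min_alt_reads: int = 2, max_normal_af: float = 0.0,
                  max_p: float = 1e-3,
                  stats_out: CallStats | None = None) -> Iterator[VcfRecord]:
    """Call somatic variants from paired experimental/normal pileups.

    At each column, every non-reference base with at least ``min_alt_reads``
    supporting reads in the experimental sample and a normal allele
    fraction at most ``max_normal_af`` is tested; a VCF record is emitted
    when the Fisher p-value is at most ``max_p``.
    """
    st = stats_out if stats_out is not None else CallStats()
    norm_by_pos = {(c.chrom, c.pos): c for c in normal}
    for col in experimental:
        ncol = norm_by_pos.get((col.chrom, col.pos))
        if ncol is None:
            st.no_normal += 1
            continue
        if col.ref_base not in BASES:
            continue
        exp_ref = col.counts[col.ref_base]
        norm_ref = ncol.counts[ncol.ref_base]
        for alt in BASES:
            if alt == col.ref_base:
                continue
            exp_alt = col.counts[alt]
            if exp_alt < min_alt_reads:
                continue
            if ncol.allele_fraction(alt) > max_normal_af:
                continue
            st.tested += 1
            p = fisher_somatic_p(exp_alt, exp_ref, ncol.counts[alt], norm_ref)
            if p <= max_p:
                st.called += 1
                yield VcfRecord(
                    chrom=col.chrom, start=col.pos, id=".",
                    ref=col.ref_base, alts=(alt,), qual=".", filter=".",
                    info={
                        "PVAL": "%g" % p,
                        "DP_EXP": str(col.depth),
                        "DP_NORM": str(ncol.depth),
                        "AF_EXP": "%g" % col.allele_fraction(alt),
                        "AF_NORM": "%g" % ncol.allele_fraction(alt),
                    },
                )
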