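"""Enumerate observed haplotypes over a genomic interval from phased VCF."""

from __future__ import annotations

from typing import Iterable

from ..formats.core import GenomicInterval
from ..formats.vcf import VcfRecord
from ..seqcore import Sequence


def haplotype_generator(records: Iterable[VcfRecord], ref: dict[str, Sequence],
                        region: GenomicInterval,
                        assume_phased: bool = False) -> list[tuple[Sequence, int]]:
    """Build every sample haplotype across ``region`` and merge duplicates.

    Variant alleles (SNVs and simple indels) are substituted into the
    reference slice right-to-left so earlier coordinates stay valid.
    Unphased heterozygous genotypes are an error unless ``assume_phased``.
    Returns (sequence, count) pairs sorted by descending count, then by
    sequence for determinism.
    """
    if region.chrom not in ref:
        raise ValueError(f"reference lacks chromosome {region.chrom!r}")
    records = list(records)
    base = ref[region.chrom].seq[region.start:region.end]
    in_region = [
        r for r in records
        if r.chrom == region.chrom and r.start >= region.start
        and r.end <= region.end
    ]
    in_region.sort(key=lambda r: -r.start)  # right-to-left application

    n_haps: int | None = None
    parsed = []
    for r in in_region:
        gts = r.genotypes()
        if not gts:
            raise ValueError(f"record at {r.chrom}:{r.start + 1} has no genotypes")
        for g in gts:
            if g.is_missing:
                raise ValueError(
                    f"missing genotype at {r.chrom}:{r.start + 1}")
            if len(g.alleles) > 1 and not g.phased and len(set(g.alleles)) > 1 \
                    and not assume_phased:
                raise ValueError(
                    f"unphased heterozygous genotype at {r.chrom}:{r.start + 1}")
        flat = [a for g in gts for a in g.alleles]
        if n_haps is None:
            n_haps = len(flat)
        elif len(flat) != n_haps:
            raise ValueError("inconsistent ploidy/sample count across records")
        parsed.append((r, flat))

    if n_haps is None:
        n_haps = 2 * _count_samples(records)

    haplotypes: dict[str, int] = {}
    for h in range(n_haps):
        seq = base
        for r, flat in parsed:
            allele = flat[h]
            if allele == 0:
                continue
            off = r.start - region.start
            seq = seq[:off] + r.alts[allele - 1] + seq[off + len(r.ref):]
        haplotypes[seq] = haplotypes.get(seq, 0) + 1

    ranked = sorted(haplotypes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        (Sequence(f"hap_{i}", seq), count) for i, (seq, count) in enumerate(ranked)
    ]


def _count_samples(records) -> int:
    for r in records:
        return len(r.samples)
    return 0
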