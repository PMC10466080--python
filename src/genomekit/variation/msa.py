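"""SNVs from a multiple alignment in FASTA format."""

from __future__ import annotations

from typing import Sequence as Seq

from ..formats.vcf import VcfRecord
from ..seqcore import GAP, Sequence


def multi_fa_to_vcf(aln: Seq[Sequence], ref_name: str,
                    ) -> tuple[list[VcfRecord], int]:
    """Walk alignment columns and emit merged-ALT SNV records.

    The reference coordinate advances on non-gap reference bases.  A
    record is emitted where the reference base and at least one other
    sequence's base are both non-gap and differ (case-folded); ALTs at a
    site are merged into one record.  Columns containing any gap are
    counted and reported, never emitted.  Returns (records, gap columns).
    """
    if not aln:
        raise ValueError("empty alignment")
    lengths = {len(s.seq) for s in aln}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    by_key = {s.name.split()[0]: s for s in aln}
    if ref_name not in by_key:
        raise ValueError(f"reference {ref_name!r} not in alignment")
    ref = by_key[ref_name]
    others = [s for s in aln if s is not ref]

    records: list[VcfRecord] = []
    gap_columns = 0
    ref_pos = 0  # 0-based coordinate in the ungapped reference
    for col in range(len(ref.seq)):
        ref_base = ref.seq[col]
        col_bases = [s.seq[col] for s in others]
        if ref_base == GAP or any(b == GAP for b in col_bases):
            gap_columns += 1
            if ref_base != GAP:
                ref_pos += 1
            continue
        alts = sorted({
            b.upper() for b in col_bases if b.upper() != ref_base.upper()
        })
        if alts:
            records.append(VcfRecord(
                chrom=ref_name, start=ref_pos, id=".",
                ref=ref_base.upper(), alts=tuple(alts),
                qual=".", filter=".", info={},
            ))
        ref_pos += 1
    return records, gap_columns
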