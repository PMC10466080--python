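"""Coordinate lifting between assemblies through chain alignments.

A :class:`ChainIndex` holds a range tree over the target-side spans of all
chains plus per-chain cumulative block offsets, so a single position maps
in O(log blocks).  Interval lifting reports one of four statuses:

``lifted``
    exactly one chain carries at least ``min_match`` of the interval's
    bases (or one chain's score strictly dominates all other usable ones).
``partial``
    some bases map but no chain reaches ``min_match``.
``unmapped``
    no base of the interval falls in an aligned block.
``ambiguous``
    several usable chains with tied scores.

The lifted interval spans the minimum to maximum mapped query base, so
internal unaligned stretches widen rather than split the output; strict
mode refuses those cases instead.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable

from .formats.bed import BedRecord
from .formats.chain import ChainAlignment
from .formats.core import GenomicInterval
from .formats.sam import SamRecord
from .formats.vcf import VcfRecord
from .intervals import IntervalIndex
from .seqcore import Sequence, seq_equal

LIFTED = "lifted"
UNMAPPED = "unmapped"
PARTIAL = "partial"
AMBIGUOUS = "ambiguous"


class _CompiledChain:
    """A chain with cumulative block offsets for binary-searched mapping."""

    __slots__ = ("chain", "t_starts", "q_starts", "sizes", "chrom", "start", "end")

    def __init__(self, chain: ChainAlignment):
        chain.validate()
        self.chain = chain
        self.t_starts: list[int] = []
        self.q_starts: list[int] = []  # strand-local
        self.sizes: list[int] = []
        # target-side interval protocol, for the range tree
        self.chrom = chain.t_name
        self.start = chain.t_start
        self.end = chain.t_end
        t, q = chain.t_start, chain.q_start
        for size, dt, dq in chain.blocks:
            self.t_starts.append(t)
            self.q_starts.append(q)
            self.sizes.append(size)
            t += size + (dt or 0)
            q += size + (dq or 0)

    def map_local(self, t_pos: int) -> int | None:
        """Strand-local query coordinate for a target position, None in gaps."""
        c = self.chain
        if not c.t_start <= t_pos < c.t_end:
            raise ValueError(
                f"position {t_pos} outside chain {c.chain_id} target span "
                f"[{c.t_start}, {c.t_end})"
            )
        i = bisect.bisect_right(self.t_starts, t_pos) - 1
        off = t_pos - self.t_starts[i]
        if off < self.sizes[i]:
            return self.q_starts[i] + off
        return None

    def map_position(self, t_pos: int) -> int | None:
        """Forward-strand query coordinate for a target position, None in gaps."""
        q_local = self.map_local(t_pos)
        if q_local is None:
            return None
        c = self.chain
        return c.q_size - q_local - 1 if c.q_strand == "-" else q_local

    def mapped_extent(self, start: int, end: int) -> tuple[int, int | None, int | None]:
        """(mapped base count, min local q, max local q + 1) over [start, end)."""
        mapped = 0
        lo: int | None = None
        hi: int | None = None
        i = max(bisect.bisect_right(self.t_starts, start) - 1, 0)
        for j in range(i, len(self.sizes)):
            bs, sz = self.t_starts[j], self.sizes[j]
            if bs >= end:
                break
            a, b = max(start, bs), min(end, bs + sz)
            if a < b:
                mapped += b - a
                qa = self.q_starts[j] + (a - bs)
                qb = qa + (b - a)
                if lo is None:
                    lo = qa
                hi = qb
        return mapped, lo, hi


def map_position(chain: ChainAlignment, t_pos: int) -> int | None:
    """Map one target position through a chain (forward query coordinates)."""
    return _CompiledChain(chain).map_position(t_pos)


@dataclass
class LiftResult:
    status: str
    interval: GenomicInterval | None
    mapped_fraction: float
    chain_id: int | None


class ChainIndex:
    """Range tree over chain target spans with compiled per-chain offsets."""

    def __init__(self, chains: Iterable[ChainAlignment]):
        self._compiled = [_CompiledChain(c) for c in chains]
        self._index = IntervalIndex(self._compiled)

    def __len__(self) -> int:
        return len(self._compiled)

    @property
    def chains(self) -> list[ChainAlignment]:
        return [c.chain for c in self._compiled]

    def candidates(self, iv: GenomicInterval) -> list[_CompiledChain]:
        return self._index.query(iv.chrom, iv.start, iv.end)

    def lift(self, iv: GenomicInterval, min_match: float = 0.95,
             strict: bool = False) -> LiftResult:
        return lift_interval(self, iv, min_match=min_match, strict=strict)


def _lift_through(cc: _CompiledChain, iv: GenomicInterval) -> tuple[float, GenomicInterval | None]:
    mapped, lo, hi = cc.mapped_extent(iv.start, iv.end)
    if mapped == 0 or lo is None or hi is None:
        return 0.0, None
    c = cc.chain
    if c.q_strand == "-":
        # forward coordinates of strand-local range [lo, hi)
        start, end = c.q_size - hi, c.q_size - lo
    else:
        start, end = lo, hi
    strand = iv.strand
    if strand in "+-" and c.q_strand == "-":
        strand = "-" if strand == "+" else "+"
    return mapped / len(iv), GenomicInterval(c.q_name, start, end, strand)


def lift_interval(index: ChainIndex, iv: GenomicInterval,
                  min_match: float = 0.95, strict: bool = False) -> LiftResult:
    """Lift one interval; see the module docstring for the status contract."""
    if not 0 < min_match <= 1:
        raise ValueError(f"min_match must be in (0, 1], got {min_match}")
    if len(iv) == 0:
        return LiftResult(UNMAPPED, None, 0.0, None)
    results = []
    for cc in index.candidates(iv):
        frac, lifted = _lift_through(cc, iv)
        if lifted is not None:
            results.append((frac, cc.chain.score, cc.chain.chain_id, lifted))
    if not results:
        return LiftResult(UNMAPPED, None, 0.0, None)
    usable = [r for r in results if r[0] >= min_match]
    if not usable:
        best = max(results, key=lambda r: r[0])
        return LiftResult(PARTIAL, None, best[0], None)
    if len(usable) > 1:
        by_score = sorted(usable, key=lambda r: -r[1])
        if by_score[0][1] == by_score[1][1]:
            return LiftResult(AMBIGUOUS, None, by_score[0][0], None)
        chosen = by_score[0]
    else:
        chosen = usable[0]
    frac, _, chain_id, lifted = chosen
    if strict and frac < 1.0:
        return LiftResult(PARTIAL, None, frac, None)
    return LiftResult(LIFTED, lifted, frac, chain_id)


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap target and query so the chain lifts in the opposite direction.

    The new target strand is normalized to ``+``: for a ``-`` strand query
    the block list is reversed and both coordinate pairs are flipped to
    the other end of their sequence.
    """
    chain.validate()
    sizes = [b[0] for b in chain.blocks]
    dts = [b[1] for b in chain.blocks[:-1]]
    dqs = [b[2] for b in chain.blocks[:-1]]
    if chain.q_strand == "+":
        new_blocks = [
            (sizes[i], dqs[i] if i < len(dqs) else None,
             dts[i] if i < len(dts) else None)
            for i in range(len(sizes))
        ]
        inv = ChainAlignment(
            score=chain.score,
            t_name=chain.q_name, t_size=chain.q_size, t_strand="+",
            t_start=chain.q_start, t_end=chain.q_end,
            q_name=chain.t_name, q_size=chain.t_size, q_strand="+",
            q_start=chain.t_start, q_end=chain.t_end,
            chain_id=chain.chain_id, blocks=new_blocks,
        )
    else:
        # reverse block order; gaps travel with the boundary they precede
        n = len(sizes)
        new_blocks = []
        for j in range(n):
            i = n - 1 - j
            if j < n - 1:
                gap_i = i - 1  # gap between old blocks i-1 and i
                new_blocks.append((sizes[i], dqs[gap_i], dts[gap_i]))
            else:
                new_blocks.append((sizes[i], None, None))
        inv = ChainAlignment(
            score=chain.score,
            t_name=chain.q_name, t_size=chain.q_size, t_strand="+",
            t_start=chain.q_size - chain.q_end,
            t_end=chain.q_size - chain.q_start,
            q_name=chain.t_name, q_size=chain.t_size, q_strand="-",
            q_start=chain.t_size - chain.t_end,
            q_end=chain.t_size - chain.t_start,
            chain_id=chain.chain_id, blocks=new_blocks,
        )
    inv.validate()
    return inv


# ---------------------------------------------------------------------------
# whole-file lifting
# ---------------------------------------------------------------------------

def lift_records(index: ChainIndex, records: Iterable, fmt: str,
                 min_match: float = 0.95, strict: bool = False,
                 new_ref: dict[str, Sequence] | None = None):
    """Yield ``("lifted", record)`` or ``("unmapped", record, reason)``.

    Every input record lands in exactly one output stream.  VCF records
    are re-checked against ``new_ref`` when one is supplied; SAM records
    whose alignment would need CIGAR surgery (span crossing a block edge,
    or a strand flip) are unmapped with reason ``cigar_split``.
    """
    for rec in records:
        iv = getattr(rec, "interval", None)
        if iv is None:
            yield "unmapped", rec, "no_coordinates"
            continue
        res = lift_interval(index, iv, min_match=min_match, strict=strict)
        if res.status != LIFTED:
            reason = res.status if res.status != UNMAPPED else "no_chain"
            yield "unmapped", rec, reason
            continue
        out = res.interval
        if fmt == "bed":
            new = BedRecord(out.chrom, out.start, out.end, name=rec.name,
                            score=rec.score,
                            strand=(out.strand if rec.strand else None),
                            extras=rec.extras, n_cols=rec.n_cols)
            yield "lifted", new
        elif fmt == "vcf":
            if len(out) != len(rec.ref):
                yield "unmapped", rec, "length_change"
                continue
            if new_ref is not None:
                target = new_ref.get(out.chrom)
                if target is None or not seq_equal(
                        target.seq[out.start:out.end], rec.ref):
                    yield "unmapped", rec, "ref_mismatch"
                    continue
            new = VcfRecord(chrom=out.chrom, start=out.start, id=rec.id,
                            ref=rec.ref, alts=rec.alts, qual=rec.qual,
                            filter=rec.filter, info=dict(rec.info),
                            format=rec.format, samples=rec.samples)
            yield "lifted", new
        elif fmt == "sam":
            # only a contiguous same-strand mapping avoids alignment surgery
            if len(out) != iv.end - iv.start or res.mapped_fraction < 1.0 \
                    or out.strand != iv.strand:
                yield "unmapped", rec, "cigar_split"
                continue
            new = SamRecord(qname=rec.qname, flag=rec.flag, rname=out.chrom,
                            pos=out.start, mapq=rec.mapq, cigar=rec.cigar,
                            rnext=rec.rnext, pnext=rec.pnext, tlen=rec.tlen,
                            seq=rec.seq, qual=rec.qual, tags=rec.tags)
            yield "lifted", new
        else:
            raise ValueError(f"unsupported lift format {fmt!r}")
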