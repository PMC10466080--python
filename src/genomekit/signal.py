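"""Coverage tracks from alignments and arithmetic/smoothing over WIG tracks.

Depth counting follows standard pileup-depth semantics: CIGAR operations
M, =, X and D cover the reference (a deletion still spans its columns),
while N (spliced gaps), I, S and H do not.  Only primary mapped reads are
counted.  Missing values propagate through arithmetic and never masquerade
as zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .formats.sam import SamRecord
from .formats.wig import WigTrack

COVERING_OPS = frozenset("M=XD")


def coverage_vectors(sam_records: Iterable[SamRecord],
                     chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-chromosome integer depth vectors (difference-array accumulation)."""
    diffs = {c: np.zeros(size + 1, dtype=np.int64)
             for c, size in chrom_sizes.items()}
    for rec in sam_records:
        if rec.is_unmapped or not rec.is_primary or rec.cigar is None:
            continue
        if rec.rname not in diffs:
            raise ValueError(f"chromosome {rec.rname!r} absent from chrom.sizes")
        d = diffs[rec.rname]
        pos = rec.pos
        for length, op in rec.cigar:
            if op in COVERING_OPS:
                if pos + length > chrom_sizes[rec.rname]:
                    raise ValueError(
                        f"{rec.qname}: alignment past end of {rec.rname} "
                        f"({pos + length} > {chrom_sizes[rec.rname]})")
                d[pos] += 1
                d[pos + length] -= 1
                pos += length
            elif op == "N":
                pos += length
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def sam_to_wig(sam_records: Iterable[SamRecord],
               chrom_sizes: dict[str, int]) -> list[WigTrack]:
    """Base-resolution depth as fixedStep step=1 span=1 tracks."""
    vectors = coverage_vectors(sam_records, chrom_sizes)
    return [
        WigTrack(chrom, 0, 1, 1, [float(v) for v in vec])
        for chrom, vec in vectors.items()
    ]


def _to_array(values: Sequence[float | None]) -> np.ndarray:
    return np.array([np.nan if v is None else float(v) for v in values])


def _from_array(arr: np.ndarray) -> list[float | None]:
    return [None if math.isnan(v) else float(v) for v in arr]


def _check_grids(a: list[WigTrack], b: list[WigTrack]) -> None:
    if len(a) != len(b):
        raise ValueError(f"track count mismatch: {len(a)} vs {len(b)}")
    for ta, tb in zip(a, b):
        if (ta.chrom, ta.start, ta.step, ta.span, len(ta.values)) != \
                (tb.chrom, tb.start, tb.step, tb.span, len(tb.values)):
            raise ValueError(f"grid mismatch on chromosome {ta.chrom!r}")


def smooth_values(values: Sequence[float | None], window: int) -> list[float | None]:
    """Centered moving average over the non-missing neighbors in the window.

    Positions whose whole window is missing stay missing; windows are
    truncated at track edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    arr = _to_array(values)
    ok = ~np.isnan(arr)
    filled = np.where(ok, arr, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(ok.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return _from_array(out)


def wig_math(a: list[WigTrack], b: list[WigTrack] | None = None,
             op: str = "add", window: int = 5,
             scalar: float = 1.0) -> list[WigTrack]:
    """Element-wise arithmetic or smoothing over WIG tracks.

    Binary operations (add, subtract, multiply, divide) require identical
    grids; a missing operand makes the result missing, as does division
    by zero.  Unary operations are ``smooth`` (odd centered window) and
    ``scale`` (multiply by a scalar).
    """
    binary = {"add", "subtract", "multiply", "divide"}
    if op in binary:
        if b is None:
            raise ValueError(f"operation {op!r} needs two track sets")
        _check_grids(a, b)
        out = []
        for ta, tb in zip(a, b):
            x, y = _to_array(ta.values), _to_array(tb.values)
            with np.errstate(invalid="ignore", divide="ignore"):
                if op == "add":
                    r = x + y
                elif op == "subtract":
                    r = x - y
                elif op == "multiply":
                    r = x * y
                else:
                    r = x / y
                    r[y == 0] = np.nan
            out.append(WigTrack(ta.chrom, ta.start, ta.step, ta.span,
                                _from_array(r)))
        return out
    if op == "smooth":
        return [WigTrack(t.chrom, t.start, t.step, t.span,
                         smooth_values(t.values, window)) for t in a]
    if op == "scale":
        return [WigTrack(t.chrom, t.start, t.step, t.span,
                         _from_array(_to_array(t.values) * scalar)) for t in a]
    raise ValueError(f"unknown operation {op!r}")
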