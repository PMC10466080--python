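"""BED (3-12 column) and BEDPE codecs.

Columns beyond the six standard ones are preserved verbatim as opaque
strings; the column count must be constant within a file.  Score is kept
as the verbatim string so that round-trips are byte-faithful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import FormatError, GenomicInterval, open_sink, open_stream


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None
    extras: tuple[str, ...] = ()
    n_cols: int = 3

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid BED interval {self.chrom}:{self.start}-{self.end}")
        if self.n_cols == 3 and (self.name is not None or self.extras):
            # infer the column count when the caller did not set it
            self.n_cols = 3 + sum(
                x is not None for x in (self.name, self.score, self.strand)
            ) + len(self.extras)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand or ".")

    def __len__(self) -> int:
        return self.end - self.start

    def to_line(self) -> str:
        cols = [self.chrom, str(self.start), str(self.end)]
        optional = [self.name, self.score, self.strand, *self.extras]
        for i in range(self.n_cols - 3):
            v = optional[i] if i < len(optional) else None
            cols.append("." if v is None else str(v))
        return "\t".join(cols)


def parse_bed_line(line: str, path: str = "<stream>", line_no: int = 0) -> BedRecord:
    cols = line.split("\t")
    if len(cols) == 1:
        cols = line.split()
    if not 3 <= len(cols) <= 12:
        raise FormatError(
            f"BED requires 3-12 columns, got {len(cols)}", path=path,
            line_no=line_no, text=line,
        )
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError:
        raise FormatError("non-integer BED coordinates", path=path,
                          line_no=line_no, text=line) from None
    if end < start:
        raise FormatError(f"end {end} < start {start}", path=path,
                          line_no=line_no, text=line)
    return BedRecord(
        chrom=cols[0], start=start, end=end,
        name=cols[3] if len(cols) > 3 else None,
        score=cols[4] if len(cols) > 4 else None,
        strand=cols[5] if len(cols) > 5 else None,
        extras=tuple(cols[6:]),
        n_cols=len(cols),
    )


def read_bed(source: str | io.TextIOBase) -> Iterator[BedRecord]:
    """Stream BED records; the column count must be constant within the file."""
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    expected_cols: int | None = None
    for line_no, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        rec = parse_bed_line(line, path, line_no)
        if expected_cols is None:
            expected_cols = rec.n_cols
        elif rec.n_cols != expected_cols:
            raise FormatError(
                f"inconsistent column count: {rec.n_cols} vs {expected_cols}",
                path=path, line_no=line_no, text=line,
            )
        yield rec


def write_bed(sink: str | io.TextIOBase, records: Iterable[BedRecord]) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    n_cols: int | None = None
    try:
        for r in records:
            if n_cols is None:
                n_cols = r.n_cols
            elif r.n_cols != n_cols:
                raise FormatError(
                    f"mixed column counts in one BED file: {r.n_cols} vs {n_cols}"
                )
            out.write(r.to_line() + "\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()


@dataclass
class BedPeRecord:
    """A paired-interval record; the two feet may sit on different chromosomes."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str | None = None
    score: str | None = None
    strand1: str | None = None
    strand2: str | None = None
    extras: tuple[str, ...] = ()
    n_cols: int = 6

    def __post_init__(self):
        for c, s, e in ((self.chrom1, self.start1, self.end1),
                        (self.chrom2, self.start2, self.end2)):
            if s < 0 or e < s:
                raise ValueError(f"invalid BEDPE foot {c}:{s}-{e}")
        if self.n_cols == 6 and (self.name is not None or self.extras):
            self.n_cols = 6 + sum(
                x is not None
                for x in (self.name, self.score, self.strand1, self.strand2)
            ) + len(self.extras)

    @property
    def foot_a(self) -> GenomicInterval:
        return GenomicInterval(self.chrom1, self.start1, self.end1, self.strand1 or ".")

    @property
    def foot_b(self) -> GenomicInterval:
        return GenomicInterval(self.chrom2, self.start2, self.end2, self.strand2 or ".")

    def to_line(self) -> str:
        cols = [self.chrom1, str(self.start1), str(self.end1),
                self.chrom2, str(self.start2), str(self.end2)]
        optional = [self.name, self.score, self.strand1, self.strand2, *self.extras]
        for i in range(self.n_cols - 6):
            v = optional[i] if i < len(optional) else None
            cols.append("." if v is None else str(v))
        return "\t".join(cols)


def read_bedpe(source: str | io.TextIOBase) -> Iterator[BedPeRecord]:
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    for line_no, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise FormatError(f"BEDPE requires >= 6 columns, got {len(cols)}",
                              path=path, line_no=line_no, text=line)
        try:
            rec = BedPeRecord(
                chrom1=cols[0], start1=int(cols[1]), end1=int(cols[2]),
                chrom2=cols[3], start2=int(cols[4]), end2=int(cols[5]),
                name=cols[6] if len(cols) > 6 else None,
                score=cols[7] if len(cols) > 7 else None,
                strand1=cols[8] if len(cols) > 8 else None,
                strand2=cols[9] if len(cols) > 9 else None,
                extras=tuple(cols[10:]),
                n_cols=len(cols),
            )
        except ValueError as e:
            raise FormatError(str(e), path=path, line_no=line_no, text=line) from None
        yield rec


def write_bedpe(sink: str | io.TextIOBase, records: Iterable[BedPeRecord]) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for r in records:
            out.write(r.to_line() + "\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
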