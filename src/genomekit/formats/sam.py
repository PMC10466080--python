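"""SAM text codec (binary BAM is an adapter seam, not implemented here).

POS is converted to 0-based on read; the alignment end is derived from
reference-consuming CIGAR operations (M, D, N, =, X).  Optional tags are
carried as opaque, order-preserved strings.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import FormatError, GenomicInterval, open_sink, open_stream

CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def parse_cigar(cigar: str) -> list[tuple[int, str]] | None:
    if cigar == "*":
        return None
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return [(int(n), o) for n, o in ops]


def cigar_to_string(cigar: list[tuple[int, str]] | None) -> str:
    if cigar is None:
        return "*"
    return "".join(f"{n}{o}" for n, o in cigar)


def cigar_reference_span(cigar: list[tuple[int, str]] | None) -> int:
    if cigar is None:
        return 0
    return sum(n for n, op in cigar if op in REF_CONSUMING)


def cigar_query_length(cigar: list[tuple[int, str]] | None) -> int:
    if cigar is None:
        return 0
    return sum(n for n, op in cigar if op in QUERY_CONSUMING)


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int  # 0-based leftmost mapping position; -1 when unmapped ('*'/0)
    mapq: int
    cigar: list[tuple[int, str]] | None
    rnext: str = "*"
    pnext: int = -1
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        if (self.cigar is not None and self.seq != "*"
                and cigar_query_length(self.cigar) != len(self.seq)):
            raise ValueError(
                f"{self.qname}: CIGAR query length {cigar_query_length(self.cigar)} "
                f"!= sequence length {len(self.seq)}"
            )

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED) or self.rname == "*" or self.pos < 0

    @property
    def is_primary(self) -> bool:
        return not self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def chrom(self) -> str:
        return self.rname

    @property
    def start(self) -> int:
        return self.pos

    @property
    def end(self) -> int:
        return self.pos + cigar_reference_span(self.cigar)

    @property
    def interval(self) -> GenomicInterval | None:
        if self.is_unmapped:
            return None
        return GenomicInterval(self.rname, self.start, self.end,
                               "-" if self.is_reverse else "+")

    def to_line(self) -> str:
        cols = [
            self.qname, str(self.flag), self.rname, str(self.pos + 1),
            str(self.mapq), cigar_to_string(self.cigar), self.rnext,
            str(self.pnext + 1), str(self.tlen), self.seq, self.qual,
        ]
        cols.extend(self.tags)
        return "\t".join(cols)


def parse_sam_line(line: str, path: str = "<stream>", line_no: int = 0) -> SamRecord:
    cols = line.split("\t")
    if len(cols) < 11:
        raise FormatError(f"SAM requires >= 11 columns, got {len(cols)}",
                          path=path, line_no=line_no, text=line)
    try:
        return SamRecord(
            qname=cols[0], flag=int(cols[1]), rname=cols[2],
            pos=int(cols[3]) - 1, mapq=int(cols[4]),
            cigar=parse_cigar(cols[5]), rnext=cols[6],
            pnext=int(cols[7]) - 1, tlen=int(cols[8]),
            seq=cols[9], qual=cols[10], tags=tuple(cols[11:]),
        )
    except ValueError as e:
        raise FormatError(str(e), path=path, line_no=line_no, text=line) from None


class SamReader:
    """Streaming SAM reader; ``@`` header lines are captured before iteration."""

    def __init__(self, source: str | io.TextIOBase):
        self._stream = open_stream(source) if isinstance(source, str) else source
        self._path = source if isinstance(source, str) else "<stream>"
        self.header: list[str] = []
        self._line_no = 0
        self._pending: str | None = None
        for line in self._stream:
            self._line_no += 1
            line = line.rstrip("\n")
            if line.startswith("@"):
                self.header.append(line)
            else:
                self._pending = line
                break

    def reference_lengths(self) -> dict[str, int]:
        out = {}
        for line in self.header:
            if line.startswith("@SQ"):
                fields = dict(f.split(":", 1) for f in line.split("\t")[1:] if ":" in f)
                if "SN" in fields and "LN" in fields:
                    out[fields["SN"]] = int(fields["LN"])
        return out

    def __iter__(self) -> Iterator[SamRecord]:
        if self._pending is not None:
            if self._pending:
                yield parse_sam_line(self._pending, self._path, self._line_no)
            self._pending = None
        for line in self._stream:
            self._line_no += 1
            line = line.rstrip("\n")
            if not line:
                continue
            yield parse_sam_line(line, self._path, self._line_no)


def read_sam(source: str | io.TextIOBase) -> SamReader:
    return SamReader(source)


def sam_header(chrom_sizes: dict[str, int], sort_order: str = "unknown") -> list[str]:
    lines = [f"@HD\tVN:1.6\tSO:{sort_order}"]
    lines.extend(f"@SQ\tSN:{name}\tLN:{size}" for name, size in chrom_sizes.items())
    return lines


def write_sam(sink: str | io.TextIOBase, records: Iterable[SamRecord],
              header: Iterable[str] | None = None) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        if header is not None:
            for line in header:
                out.write(line + "\n")
        for r in records:
            out.write(r.to_line() + "\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
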