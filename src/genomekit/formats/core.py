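"""Shared primitives for the format codecs.

Every format adapts to one internal coordinate convention: 0-based,
half-open ``[start, end)``.  One-based formats (VCF, SAM, WIG, GTF) are
converted on read and restored on write; conversions live exclusively in
the parsers and serializers.
"""

from __future__ import annotations

import gzip
import io
import sys
from dataclasses import dataclass


class FormatError(ValueError):
    """A malformed record; carries file name, line number and offending text."""

    def __init__(self, message: str, path: str | None = None, line_no: int | None = None,
                 text: str | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line_no is not None:
            loc += f"line {line_no}: "
        detail = f" [{text!r}]" if text else ""
        super().__init__(f"{loc}{message}{detail}")
        self.path = path
        self.line_no = line_no
        self.text = text


STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval; ``.`` means unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: adjacent intervals share a boundary but do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


GZIP_MAGIC = b"\x1f\x8b"


def open_stream(path: str) -> io.TextIOBase:
    """Open a text stream, transparently decompressing gzip.

    Detection is by the gzip magic bytes, so a gzipped file misnamed
    without ``.gz`` is still decompressed; a ``.gz`` path whose content is
    not gzip is an error (the extension promised compression).
    ``-`` means stdin.
    """
    if path == "-":
        return sys.stdin
    raw = open(path, "rb")
    head = raw.peek(2)[:2] if isinstance(raw, io.BufferedReader) else b""
    if head == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(raw, "rb"))  # type: ignore[arg-type]
    if path.endswith(".gz"):
        raw.close()
        raise FormatError("file has .gz extension but is not gzip-compressed", path=path)
    return io.TextIOWrapper(raw)


def open_sink(path: str) -> io.TextIOBase:
    """Open a text sink; ``.gz`` suffix selects gzip output, ``-`` means stdout."""
    if path == "-":
        return sys.stdout
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "wb"))  # type: ignore[arg-type]
    return open(path, "w")


def fmt_float(x: float) -> str:
    """Canonical float serialization (``%g``)."""
    return "%g" % x
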