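"""Streaming FASTQ reader/writer (Phred+33 qualities)."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator

from .core import FormatError, open_sink, open_stream


@dataclass
class FastqRecord:
    name: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"{self.name}: sequence length {len(self.seq)} != quality length {len(self.qual)}"
            )


def read_fastq(source: str | io.TextIOBase) -> Iterator[FastqRecord]:
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    line_no = 0
    it = iter(stream)
    while True:
        try:
            header = next(it)
        except StopIteration:
            return
        line_no += 1
        header = header.rstrip("\n")
        if not header:
            continue
        if not header.startswith("@"):
            raise FormatError("expected @ header", path=path, line_no=line_no, text=header)
        try:
            seq = next(it).rstrip("\n")
            plus = next(it).rstrip("\n")
            qual = next(it).rstrip("\n")
        except StopIteration:
            raise FormatError("truncated FASTQ record", path=path, line_no=line_no) from None
        line_no += 3
        if not plus.startswith("+"):
            raise FormatError("expected + separator", path=path, line_no=line_no - 1, text=plus)
        try:
            yield FastqRecord(header[1:], seq, qual)
        except ValueError as e:
            raise FormatError(str(e), path=path, line_no=line_no) from None


def write_fastq(sink: str | io.TextIOBase, records: Iterable[FastqRecord]) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for r in records:
            out.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
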