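"""Streaming FASTA reader/writer with transparent gzip support."""

from __future__ import annotations

import io
from typing import Iterable, Iterator

from ..seqcore import Sequence, validate_seq
from .core import FormatError, open_sink, open_stream


def read_fasta(source: str | io.TextIOBase) -> Iterator[Sequence]:
    """Yield :class:`Sequence` records one at a time.

    Memory is bounded by one record; the sequence name is the full header
    line after ``>``.
    """
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    name: str | None = None
    chunks: list[str] = []
    for line_no, line in enumerate(stream, 1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                yield Sequence(name, "".join(chunks))
            name = line[1:].strip()
            if not name:
                raise FormatError("empty FASTA header", path=path, line_no=line_no)
            chunks = []
        else:
            if name is None:
                raise FormatError(
                    "sequence data before first header", path=path,
                    line_no=line_no, text=line,
                )
            try:
                validate_seq(line, name)
            except ValueError as e:
                raise FormatError(str(e), path=path, line_no=line_no, text=line) from None
            chunks.append(line)
    if name is not None:
        yield Sequence(name, "".join(chunks))


def write_fasta(sink: str | io.TextIOBase, seqs: Iterable[Sequence], width: int = 60) -> None:
    """Write sequences with fixed-width line wrapping (default 60)."""
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for s in seqs:
            out.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                out.write(s.seq[i : i + width] + "\n")
            if len(s.seq) == 0:
                pass  # header-only record is legal
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()


def read_fasta_dict(source: str | io.TextIOBase) -> dict[str, Sequence]:
    """Eagerly read a FASTA into an ordered name -> Sequence mapping.

    The name key is the first whitespace token of the header.
    """
    out: dict[str, Sequence] = {}
    for s in read_fasta(source):
        key = s.name.split()[0]
        if key in out:
            raise FormatError(f"duplicate sequence name {key!r}")
        out[key] = s
    return out
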