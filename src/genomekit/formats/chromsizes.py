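"""chrom.sizes: two-column TSV of chromosome name and length."""

from __future__ import annotations

import io

from .core import FormatError, open_sink, open_stream


def read_chrom_sizes(source: str | io.TextIOBase) -> dict[str, int]:
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    out: dict[str, int] = {}
    for line_no, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) < 2:
            raise FormatError("chrom.sizes needs name and length", path=path,
                              line_no=line_no, text=line)
        try:
            size = int(toks[1])
        except ValueError:
            raise FormatError("non-integer chromosome length", path=path,
                              line_no=line_no, text=line) from None
        if toks[0] in out:
            raise FormatError(f"duplicate chromosome {toks[0]!r}", path=path,
                              line_no=line_no)
        out[toks[0]] = size
    return out


def write_chrom_sizes(sink: str | io.TextIOBase, sizes: dict[str, int]) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for name, size in sizes.items():
            out.write(f"{name}\t{size}\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
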