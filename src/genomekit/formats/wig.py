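"""WIG codec (fixedStep and variableStep input, fixedStep output).

A file is read into one :class:`WigTrack` per chromosome.  The file start
coordinate is 1-based and converted to 0-based internally.  Missing values
are an explicit ``None`` sentinel, never silently 0; on output, fixedStep
blocks are split around missing runs, and re-reading such a file merges
the blocks back, restoring the sentinels.  variableStep input is
canonicalized to a step-1 dense track.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import FormatError, fmt_float, open_sink, open_stream


@dataclass
class WigTrack:
    chrom: str
    start: int  # 0-based position of values[0]
    step: int = 1
    span: int = 1
    values: list[float | None] = field(default_factory=list)

    def position(self, i: int) -> int:
        return self.start + i * self.step

    def defined(self) -> int:
        return sum(v is not None for v in self.values)


def _parse_decl(line: str, path: str, line_no: int) -> dict[str, str]:
    fields = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise FormatError("malformed WIG declaration", path=path,
                              line_no=line_no, text=line)
        k, v = tok.split("=", 1)
        fields[k] = v
    return fields


def read_wig(source: str | io.TextIOBase) -> list[WigTrack]:
    """Read a WIG file into one track per chromosome.

    Blocks on the same chromosome must share step and span and appear in
    coordinate order; gaps between blocks become missing-value runs.
    """
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    tracks: dict[str, WigTrack] = {}
    mode: str | None = None
    cur: WigTrack | None = None
    next_pos = 0
    var_span = 1
    for line_no, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            f = _parse_decl(line, path, line_no)
            chrom = f["chrom"]
            start = int(f["start"]) - 1
            step = int(f.get("step", 1))
            span = int(f.get("span", 1))
            if start < 0 or step < 1:
                raise FormatError("invalid fixedStep declaration", path=path,
                                  line_no=line_no, text=line)
            cur = tracks.get(chrom)
            if cur is None:
                cur = tracks[chrom] = WigTrack(chrom, start, step, span, [])
            else:
                if cur.step != step or cur.span != span:
                    raise FormatError(
                        f"blocks on {chrom} mix step/span", path=path,
                        line_no=line_no, text=line)
                offset = start - cur.position(len(cur.values))
                if offset < 0 or offset % step != 0:
                    raise FormatError(
                        f"blocks on {chrom} out of order or off the step grid",
                        path=path, line_no=line_no, text=line)
                cur.values.extend([None] * (offset // step))
            mode = "fixed"
        elif line.startswith("variableStep"):
            f = _parse_decl(line, path, line_no)
            chrom = f["chrom"]
            var_span = int(f.get("span", 1))
            cur = tracks.get(chrom)
            if cur is None:
                cur = tracks[chrom] = WigTrack(chrom, -1, 1, 1, [])
            mode = "variable"
        else:
            if cur is None or mode is None:
                raise FormatError("data line before WIG declaration", path=path,
                                  line_no=line_no, text=line)
            if mode == "fixed":
                try:
                    cur.values.append(float(line))
                except ValueError:
                    raise FormatError("non-numeric WIG value", path=path,
                                      line_no=line_no, text=line) from None
            else:
                toks = line.split()
                if len(toks) != 2:
                    raise FormatError("variableStep lines need position and value",
                                      path=path, line_no=line_no, text=line)
                pos = int(toks[0]) - 1
                val = float(toks[1])
                if cur.start < 0:
                    cur.start = pos
                offset = pos - cur.start
                if offset < len(cur.values) - (var_span - 1) and cur.values:
                    raise FormatError("variableStep positions out of order",
                                      path=path, line_no=line_no, text=line)
                if offset > len(cur.values):
                    cur.values.extend([None] * (offset - len(cur.values)))
                for k in range(var_span):
                    idx = offset + k
                    if idx < len(cur.values):
                        cur.values[idx] = val
                    else:
                        cur.values.append(val)
    return list(tracks.values())


def write_wig(sink: str | io.TextIOBase, tracks: Iterable[WigTrack]) -> None:
    """Write fixedStep WIG; missing runs split the output into blocks."""
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for t in tracks:
            in_block = False
            for i, v in enumerate(t.values):
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    in_block = False
                    continue
                if not in_block:
                    span = f" span={t.span}" if t.span != 1 else ""
                    out.write(
                        f"fixedStep chrom={t.chrom} start={t.position(i) + 1} "
                        f"step={t.step}{span}\n"
                    )
                    in_block = True
                out.write(fmt_float(v) + "\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
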