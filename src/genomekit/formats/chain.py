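"""UCSC CHAIN codec.

A chain is a pairwise alignment of ungapped blocks between a target and a
query assembly.  Coordinates are 0-based half-open and strand-local: on a
``-`` strand query, qStart/qEnd refer to the reverse-complemented sequence.
Block arithmetic is validated on parse; a chain whose block sums disagree
with its header extents is rejected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import FormatError, GenomicInterval, open_sink, open_stream


@dataclass
class ChainAlignment:
    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    # (size, dt, dq); dt/dq are None on the last block
    blocks: list[tuple[int, int | None, int | None]] = field(default_factory=list)

    def validate(self) -> None:
        if self.t_strand != "+":
            raise ValueError(f"chain {self.chain_id}: tStrand must be '+'")
        if self.q_strand not in "+-":
            raise ValueError(f"chain {self.chain_id}: invalid qStrand {self.q_strand!r}")
        if not self.blocks:
            raise ValueError(f"chain {self.chain_id}: no blocks")
        size_sum = sum(b[0] for b in self.blocks)
        dt_sum = sum(b[1] or 0 for b in self.blocks)
        dq_sum = sum(b[2] or 0 for b in self.blocks)
        if self.blocks[-1][1] is not None or self.blocks[-1][2] is not None:
            raise ValueError(f"chain {self.chain_id}: last block must omit dt/dq")
        if size_sum + dt_sum != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: block sums {size_sum}+{dt_sum} != "
                f"target span {self.t_end - self.t_start}"
            )
        if size_sum + dq_sum != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: block sums {size_sum}+{dq_sum} != "
                f"query span {self.q_end - self.q_start}"
            )

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.t_name, self.t_start, self.t_end)

    # aliases so chains satisfy the interval protocol on their target side
    @property
    def chrom(self) -> str:
        return self.t_name

    @property
    def start(self) -> int:
        return self.t_start

    @property
    def end(self) -> int:
        return self.t_end


def read_chains(source: str | io.TextIOBase) -> Iterator[ChainAlignment]:
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    cur: ChainAlignment | None = None
    for line_no, line in enumerate(stream, 1):
        line = line.strip()
        if line.startswith("#"):
            continue
        if not line:
            if cur is not None:
                _finish(cur, path, line_no)
                yield cur
                cur = None
            continue
        if line.startswith("chain"):
            if cur is not None:
                _finish(cur, path, line_no)
                yield cur
            f = line.split()
            if len(f) != 13:
                raise FormatError("chain header needs 13 fields", path=path,
                                  line_no=line_no, text=line)
            cur = ChainAlignment(
                score=int(f[1]), t_name=f[2], t_size=int(f[3]), t_strand=f[4],
                t_start=int(f[5]), t_end=int(f[6]), q_name=f[7], q_size=int(f[8]),
                q_strand=f[9], q_start=int(f[10]), q_end=int(f[11]),
                chain_id=int(f[12]),
            )
        else:
            if cur is None:
                raise FormatError("alignment line outside a chain", path=path,
                                  line_no=line_no, text=line)
            toks = line.split()
            if len(toks) == 1:
                cur.blocks.append((int(toks[0]), None, None))
            elif len(toks) == 3:
                cur.blocks.append((int(toks[0]), int(toks[1]), int(toks[2])))
            else:
                raise FormatError("alignment line needs 1 or 3 fields", path=path,
                                  line_no=line_no, text=line)
    if cur is not None:
        _finish(cur, path, None)
        yield cur


def _finish(chain: ChainAlignment, path: str, line_no: int | None) -> None:
    try:
        chain.validate()
    except ValueError as e:
        raise FormatError(str(e), path=path, line_no=line_no) from None


def write_chains(sink: str | io.TextIOBase, chains: Iterable[ChainAlignment]) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for c in chains:
            out.write(
                f"chain {c.score} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks:
                if dt is None:
                    out.write(f"{size}\n")
                else:
                    out.write(f"{size}\t{dt}\t{dq}\n")
            out.write("\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
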