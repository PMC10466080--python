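"""GTF codec and gene-model assembly.

Coordinates are 1-based inclusive in the file, 0-based half-open in
memory.  Only ``gene_id``, ``gene_name`` and ``transcript_id`` are parsed
out of the attribute column; the raw attribute string is preserved
verbatim for round-trips.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import FormatError, GenomicInterval, open_sink, open_stream

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class GtfRecord:
    seqname: str
    source: str
    feature: str
    start: int  # 0-based
    end: int
    score: str
    strand: str
    frame: str
    attributes: str  # verbatim attribute column

    @property
    def chrom(self) -> str:
        return self.seqname

    @property
    def interval(self) -> GenomicInterval:
        strand = self.strand if self.strand in "+-" else "."
        return GenomicInterval(self.seqname, self.start, self.end, strand)

    def attr(self, key: str) -> str | None:
        m = re.search(rf'{key}\s+"([^"]*)"', self.attributes)
        return m.group(1) if m else None

    def to_line(self) -> str:
        return "\t".join([
            self.seqname, self.source, self.feature, str(self.start + 1),
            str(self.end), self.score, self.strand, self.frame, self.attributes,
        ])


def read_gtf(source: str | io.TextIOBase) -> Iterator[GtfRecord]:
    stream = open_stream(source) if isinstance(source, str) else source
    path = source if isinstance(source, str) else "<stream>"
    for line_no, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GTF requires 9 columns, got {len(cols)}",
                              path=path, line_no=line_no, text=line)
        try:
            start, end = int(cols[3]) - 1, int(cols[4])
        except ValueError:
            raise FormatError("non-integer GTF coordinates", path=path,
                              line_no=line_no, text=line) from None
        if start < 0 or end < start:
            raise FormatError("invalid GTF coordinates", path=path,
                              line_no=line_no, text=line)
        yield GtfRecord(cols[0], cols[1], cols[2], start, end,
                        cols[5], cols[6], cols[7], cols[8])


def write_gtf(sink: str | io.TextIOBase, records: Iterable[GtfRecord]) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for r in records:
            out.write(r.to_line() + "\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()


@dataclass
class GeneModel:
    """Exon structure of one gene, assembled from GTF exon features."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


def gene_models(records: Iterable[GtfRecord]) -> list[GeneModel]:
    """Group GTF exon features by gene_id into sorted gene models."""
    genes: dict[str, GeneModel] = {}
    for r in records:
        if r.feature != "exon":
            continue
        gid = r.attr("gene_id")
        if gid is None:
            raise FormatError(f"exon feature without gene_id: {r.attributes!r}")
        g = genes.get(gid)
        if g is None:
            g = genes[gid] = GeneModel(
                gene_id=gid, gene_name=r.attr("gene_name") or gid,
                chrom=r.seqname, strand=r.strand,
            )
        elif g.chrom != r.seqname:
            raise FormatError(f"gene {gid} has exons on multiple chromosomes")
        g.exons.append(r.interval)
    for g in genes.values():
        g.exons.sort(key=lambda iv: (iv.start, iv.end))
    return list(genes.values())


def read_gene_models(source: str | io.TextIOBase) -> list[GeneModel]:
    return gene_models(read_gtf(source))
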