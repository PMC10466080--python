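"""The genomic-interval engine: range-tree index, overlap queries,
genome-order external sort, BEDPE intersection, chromosome-end distances.

Any object exposing ``chrom``, ``start`` and ``end`` (0-based half-open)
participates: BED, VCF, SAM and GTF records all satisfy the protocol, so
overlap queries run across formats without conversion.
"""

from __future__ import annotations

import heapq
import os
import tempfile
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

from .formats.bed import BedPeRecord, BedRecord, parse_bed_line
from .formats.core import FormatError, GenomicInterval, open_sink, open_stream
from .formats.sam import parse_sam_line
from .formats.vcf import parse_vcf_line


def _interval_of(record) -> tuple[str, int, int] | None:
    iv = getattr(record, "interval", record)
    if iv is None:
        return None
    return iv.chrom, iv.start, iv.end


class IntervalIndex:
    """Per-chromosome range tree over interval-bearing records.

    Query results are independent of insertion order (returned in genome
    order with input order breaking ties).  Zero-length intervals
    (insertions) overlap nothing under half-open semantics; they are
    counted but never returned.  Records without coordinates (e.g.
    unmapped SAM) are skipped and counted.
    """

    def __init__(self, records: Iterable = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.n_records = 0
        self.n_skipped = 0
        self.n_zero_length = 0
        for r in records:
            self.add(r)

    def add(self, record) -> None:
        loc = _interval_of(record)
        if loc is None:
            self.n_skipped += 1
            return
        chrom, start, end = loc
        if end <= start:
            self.n_zero_length += 1
            return
        tree = self._trees.setdefault(chrom, IntervalTree())
        tree.addi(start, end, (self.n_records, record))
        self.n_records += 1

    def query(self, chrom: str, start: int, end: int) -> list:
        """All records overlapping [start, end) on chrom, in genome order."""
        tree = self._trees.get(chrom)
        if tree is None or end <= start:
            return []
        hits = tree.overlap(start, end)
        ordered = sorted(hits, key=lambda h: (h.begin, h.end, h.data[0]))
        return [h.data[1] for h in ordered]

    def query_interval(self, iv) -> list:
        loc = _interval_of(iv)
        if loc is None:
            return []
        return self.query(*loc)

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and end > start and bool(tree.overlap(start, end))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)


def query_overlaps(index: IntervalIndex, q) -> list:
    """Records r with r.chrom == q.chrom, r.start < q.end and q.start < r.end."""
    return index.query_interval(q)


# ---------------------------------------------------------------------------
# genome order and external sort
# ---------------------------------------------------------------------------

@dataclass
class GenomeOrder:
    """Total order on (chromosome rank, start, end, record text).

    With an explicit chromosome list (chrom.sizes or FASTA order) the rank
    is positional and unknown chromosomes are an error; without one,
    chromosomes sort lexicographically.
    """

    chrom_list: Sequence[str] | None = None
    _rank: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.chrom_list is not None:
            self._rank = {c: i for i, c in enumerate(self.chrom_list)}

    def chrom_key(self, chrom: str):
        if self.chrom_list is None:
            return chrom
        try:
            return self._rank[chrom]
        except KeyError:
            raise ValueError(
                f"chromosome {chrom!r} absent from the explicit genome order"
            ) from None


_LINE_PARSERS: dict[str, Callable] = {
    "bed": parse_bed_line,
    "vcf": parse_vcf_line,
    "sam": parse_sam_line,
}


def _coord_key(fmt: str, order: GenomeOrder) -> Callable[[str], tuple]:
    parse = _LINE_PARSERS[fmt]

    def key(line: str) -> tuple:
        rec = parse(line)
        return (order.chrom_key(rec.chrom), rec.start, rec.end, line)

    return key


def _barcode_key(line: str) -> tuple:
    """Sort key for single-cell mode: the ``CB:`` token in the record name."""
    name = line.split("\t", 1)[0]
    for tok in name.split("_"):
        if tok.startswith("CB:"):
            return (tok[3:], line)
    return (name, line)


def _is_header(fmt: str, line: str) -> bool:
    if fmt == "sam":
        return line.startswith("@")
    if fmt == "vcf":
        return line.startswith("#")
    return line.startswith(("#", "track", "browser"))


def genome_sort(in_path: str, out_path: str, fmt: str,
                order: GenomeOrder | None = None, chunk_size: int = 100_000,
                by_barcode: bool = False) -> None:
    """Stable external merge sort of a BED/VCF/SAM file in genome order.

    Records are split into sorted chunks of ``chunk_size`` lines, spilled
    to temporary files and k-way merged, so memory is bounded by the chunk
    size.  Header lines are re-emitted first; record bytes are preserved.
    ``by_barcode`` sorts on the cell-barcode token of the record name
    instead of coordinates.
    """
    if fmt not in _LINE_PARSERS:
        raise ValueError(f"unsupported sort format {fmt!r}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    key = _barcode_key if by_barcode else _coord_key(fmt, order or GenomeOrder())

    headers: list[str] = []
    chunk_paths: list[str] = []
    chunk: list[str] = []

    def spill():
        chunk.sort(key=key)
        fd, path = tempfile.mkstemp(suffix=".sortchunk", text=True)
        with os.fdopen(fd, "w") as f:
            f.writelines(l + "\n" for l in chunk)
        chunk_paths.append(path)
        chunk.clear()

    stream = open_stream(in_path)
    try:
        in_header = True
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            if in_header and _is_header(fmt, line):
                headers.append(line)
                continue
            in_header = False
            key(line)  # validate (and surface unknown-chromosome errors) early
            chunk.append(line)
            if len(chunk) >= chunk_size:
                spill()
        if chunk:
            spill()

        out = open_sink(out_path)
        try:
            for h in headers:
                out.write(h + "\n")
            files = [open(p) for p in chunk_paths]
            try:
                streams = [(l.rstrip("\n") for l in f) for f in files]
                for line in heapq.merge(*streams, key=key):
                    out.write(line + "\n")
            finally:
                for f in files:
                    f.close()
        finally:
            if out_path != "-":
                out.close()
    finally:
        if in_path != "-":
            stream.close()
        for p in chunk_paths:
            os.unlink(p)


# ---------------------------------------------------------------------------
# BEDPE intersection
# ---------------------------------------------------------------------------

def bedpe_filter_overlap(bedpe: Iterable[BedPeRecord], targets: Iterable,
                         mode: str = "either-foot",
                         target_kind: str = "bed") -> Iterator[BedPeRecord]:
    """Filter BEDPE records by foot overlap with BED or BEDPE targets.

    ``either-foot`` keeps records where at least one foot overlaps any
    target; ``both-feet`` requires both.  With BEDPE targets and
    ``both-feet``, the two feet must additionally hit the two feet of a
    single target record, in either orientation.
    """
    if mode not in ("either-foot", "both-feet"):
        raise ValueError(f"unknown mode {mode!r}")
    if target_kind not in ("bed", "bedpe"):
        raise ValueError(f"unknown target kind {target_kind!r}")

    index = IntervalIndex()
    if target_kind == "bed":
        for t in targets:
            index.add(t)
    else:
        for i, t in enumerate(targets):
            index.add(_Foot(t.foot_a, (i, "a")))
            index.add(_Foot(t.foot_b, (i, "b")))

    for rec in bedpe:
        a_hits = index.query_interval(rec.foot_a)
        b_hits = index.query_interval(rec.foot_b)
        if mode == "either-foot":
            if a_hits or b_hits:
                yield rec
        elif target_kind == "bed":
            if a_hits and b_hits:
                yield rec
        else:
            a_ids = {h.tag for h in a_hits}
            b_ids = {h.tag for h in b_hits}
            # the two feet must hit the two feet of one target, either way round
            paired = any(
                ((i, "a") in a_ids and (i, "b") in b_ids)
                or ((i, "b") in a_ids and (i, "a") in b_ids)
                for i, _ in a_ids
            )
            if paired:
                yield rec


@dataclass
class _Foot:
    interval: GenomicInterval
    tag: tuple

    @property
    def chrom(self):
        return self.interval.chrom

    @property
    def start(self):
        return self.interval.start

    @property
    def end(self):
        return self.interval.end


def interval_contacts(bedpe: Iterable[BedPeRecord], queries: Iterable) -> Iterator:
    """Keep query records overlapping at least one BEDPE foot, in input order."""
    index = IntervalIndex()
    for t in bedpe:
        index.add(_Foot(t.foot_a, ()))
        index.add(_Foot(t.foot_b, ()))
    for q in queries:
        loc = _interval_of(q)
        if loc is not None and index.any_overlap(*loc):
            yield q


def bed_distance_from_chr_ends(records: Iterable[BedRecord],
                               chrom_sizes: dict[str, int]) -> Iterator[BedRecord]:
    """Annotate each record's score with min(start, size - end).

    Output records are 5-column BED (chrom, start, end, name, score).
    """
    for r in records:
        size = chrom_sizes.get(r.chrom)
        if size is None:
            raise ValueError(f"chromosome {r.chrom!r} absent from chrom.sizes")
        if r.end > size:
            raise ValueError(
                f"record {r.chrom}:{r.start}-{r.end} extends past chromosome "
                f"end {size}"
            )
        dist = min(r.start, size - r.end)
        yield BedRecord(r.chrom, r.start, r.end, name=r.name or ".",
                        score=str(dist), n_cols=5)
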