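"""VCF v4.x text codec.

POS is 1-based in the file and converted to the internal 0-based half-open
interval on read (``start = POS - 1``, ``end = start + len(REF)``); the
inverse conversion happens on write.  INFO order is preserved; per-sample
fields are kept as verbatim strings so round-trips are faithful, with GT
parsed on demand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import FormatError, GenomicInterval, open_sink, open_stream

MISSING = "."


@dataclass(frozen=True)
class Genotype:
    """Parsed GT field: allele indices (None = missing ``.``) and phasing."""

    alleles: tuple[int | None, ...]
    phased: bool

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)


@dataclass
class VcfRecord:
    chrom: str
    start: int  # 0-based; file POS is start + 1
    id: str
    ref: str
    alts: tuple[str, ...]
    qual: str = MISSING
    filter: str = MISSING
    info: dict[str, str | None] = field(default_factory=dict)
    format: tuple[str, ...] | None = None
    samples: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.ref:
            raise ValueError("REF must be non-empty")
        if self.start < 0:
            raise ValueError(f"POS must be >= 1 (start {self.start})")

    @property
    def end(self) -> int:
        return self.start + len(self.ref)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    # -- variant classification -------------------------------------------
    @property
    def is_snv(self) -> bool:
        return (len(self.alts) == 1 and len(self.ref) == 1
                and len(self.alts[0]) == 1 and self.alts[0] != MISSING)

    @property
    def is_indel(self) -> bool:
        return len(self.alts) == 1 and len(self.ref) != len(self.alts[0])

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    # -- genotypes ---------------------------------------------------------
    def genotypes(self) -> list[Genotype]:
        if self.format is None or "GT" not in self.format:
            return []
        gt_idx = self.format.index("GT")
        out = []
        n_alleles = 1 + len(self.alts)
        for s in self.samples:
            gt = s.split(":")[gt_idx]
            phased = "|" in gt
            alleles = []
            for tok in gt.replace("|", "/").split("/"):
                if tok == MISSING or tok == "":
                    alleles.append(None)
                else:
                    a = int(tok)
                    if a >= n_alleles:
                        raise FormatError(
                            f"GT allele index {a} out of range for {len(self.alts)} ALT(s)"
                        )
                    alleles.append(a)
            out.append(Genotype(tuple(alleles), phased))
        return out

    def allele_frequency(self) -> float | None:
        """Alternate-allele frequency from GT fields: alt alleles / called alleles."""
        called = alt = 0
        for g in self.genotypes():
            for a in g.alleles:
                if a is not None:
                    called += 1
                    if a > 0:
                        alt += 1
        return alt / called if called else None

    # -- serialization -----------------------------------------------------
    def to_line(self) -> str:
        info = (
            ";".join(k if v is None else f"{k}={v}" for k, v in self.info.items())
            if self.info else MISSING
        )
        cols = [
            self.chrom, str(self.start + 1), self.id, self.ref,
            ",".join(self.alts) if self.alts else MISSING,
            self.qual, self.filter, info,
        ]
        if self.format is not None:
            cols.append(":".join(self.format))
            cols.extend(self.samples)
        return "\t".join(cols)


def parse_vcf_line(line: str, path: str = "<stream>", line_no: int = 0) -> VcfRecord:
    cols = line.split("\t")
    if len(cols) < 8:
        raise FormatError(f"VCF requires >= 8 columns, got {len(cols)}",
                          path=path, line_no=line_no, text=line)
    try:
        pos = int(cols[1])
    except ValueError:
        raise FormatError("non-integer POS", path=path, line_no=line_no, text=line) from None
    if pos < 1:
        raise FormatError(f"POS must be >= 1, got {pos}", path=path,
                          line_no=line_no, text=line)
    info: dict[str, str | None] = {}
    if cols[7] != MISSING:
        for item in cols[7].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                info[k] = v
            elif item:
                info[item] = None
    try:
        return VcfRecord(
            chrom=cols[0], start=pos - 1, id=cols[2], ref=cols[3],
            alts=tuple(cols[4].split(",")) if cols[4] != MISSING else (),
            qual=cols[5], filter=cols[6], info=info,
            format=tuple(cols[8].split(":")) if len(cols) > 8 else None,
            samples=tuple(cols[9:]),
        )
    except ValueError as e:
        raise FormatError(str(e), path=path, line_no=line_no, text=line) from None


class VcfReader:
    """Streaming VCF reader; header lines are captured before iteration."""

    def __init__(self, source: str | io.TextIOBase):
        self._stream = open_stream(source) if isinstance(source, str) else source
        self._path = source if isinstance(source, str) else "<stream>"
        self.header: list[str] = []
        self.samples: list[str] = []
        self._line_no = 0
        self._pending: str | None = None
        for line in self._stream:
            self._line_no += 1
            line = line.rstrip("\n")
            if line.startswith("##"):
                self.header.append(line)
            elif line.startswith("#"):
                self.header.append(line)
                cols = line.split("\t")
                self.samples = cols[9:]
                break
            else:
                # headerless VCF: treat the first data line as pending
                self._pending = line
                break

    def __iter__(self) -> Iterator[VcfRecord]:
        if self._pending is not None:
            yield parse_vcf_line(self._pending, self._path, self._line_no)
            self._pending = None
        for line in self._stream:
            self._line_no += 1
            line = line.rstrip("\n")
            if not line:
                continue
            yield parse_vcf_line(line, self._path, self._line_no)


def read_vcf(source: str | io.TextIOBase) -> VcfReader:
    return VcfReader(source)


def default_header(samples: Iterable[str] = ()) -> list[str]:
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    samples = list(samples)
    if samples:
        cols.append("FORMAT")
        cols.extend(samples)
    return ["##fileformat=VCFv4.2", "\t".join(cols)]


def write_vcf(sink: str | io.TextIOBase, records: Iterable[VcfRecord],
              header: Iterable[str] | None = None) -> None:
    out = open_sink(sink) if isinstance(sink, str) else sink
    try:
        for line in (header if header is not None else default_header()):
            out.write(line + "\n")
        for r in records:
            out.write(r.to_line() + "\n")
    finally:
        if isinstance(sink, str) and sink != "-":
            out.close()
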