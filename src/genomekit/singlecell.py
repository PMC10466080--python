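"""10x-style barcode/UMI parsing and UMI-deduplicated count matrices.

Read 1 carries the cell barcode then the UMI (defaults match 10x 3' v3:
16 + 12 bases); read 2 carries the cDNA.  Barcode extraction renames each
read 2 as ``<name>_CB:<barcode>_UMI:<umi>`` so downstream alignment-based
counting needs no side channel.  Counting assigns a read to a gene iff
its alignment overlaps exons of exactly one gene, and counts distinct
UMIs per (cell, gene) — PCR duplicates collapse to one molecule.  UMI
deduplication is exact (no Hamming-1 UMI merging), which keeps counts
deterministic; some pipelines additionally merge near-identical UMIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .formats.fastq import FastqRecord
from .formats.gtf import GeneModel
from .formats.sam import SamRecord
from .intervals import IntervalIndex


@dataclass
class BarcodeSpec:
    barcode_length: int = 16
    umi_length: int = 12
    whitelist: frozenset[str] | None = None

    def __post_init__(self):
        if self.barcode_length < 1 or self.umi_length < 1:
            raise ValueError("barcode and UMI lengths must be >= 1")
        if self.whitelist is not None:
            self.whitelist = frozenset(self.whitelist)


@dataclass
class BarcodeStats:
    total: int = 0
    exact: int = 0
    corrected: int = 0
    dropped: int = 0


_BASES = "ACGT"


def _correct_barcode(bc: str, whitelist: frozenset[str]) -> str | None:
    """Return the unique whitelist entry within Hamming distance 1, if any."""
    if bc in whitelist:
        return bc
    found: str | None = None
    for i, orig in enumerate(bc):
        for b in _BASES:
            if b == orig:
                continue
            cand = bc[:i] + b + bc[i + 1:]
            if cand in whitelist:
                if found is not None and found != cand:
                    return None  # ambiguous: two entries at distance 1
                found = cand
    return found


def _strip_mate_suffix(name: str) -> str:
    head = name.split()[0]
    return head[:-2] if head.endswith(("/1", "/2")) else head


def extract_barcodes(r1: Iterable[FastqRecord], r2: Iterable[FastqRecord],
                     spec: BarcodeSpec,
                     stats: BarcodeStats | None = None) -> Iterator[FastqRecord]:
    """Annotate read-2 records with the barcode and UMI parsed from read 1.

    With a whitelist, exact matches pass, a unique Hamming-distance-1
    match is corrected, and everything else is dropped (counted).
    Unpaired inputs (length or name mismatch) are an error.
    """
    st = stats if stats is not None else BarcodeStats()
    it1, it2 = iter(r1), iter(r2)
    while True:
        a = next(it1, None)
        b = next(it2, None)
        if a is None and b is None:
            return
        if a is None or b is None:
            raise ValueError("unpaired FASTQ files: one input ended early")
        if _strip_mate_suffix(a.name) != _strip_mate_suffix(b.name):
            raise ValueError(
                f"read name mismatch: {a.name!r} vs {b.name!r}")
        need = spec.barcode_length + spec.umi_length
        if len(a.seq) < need:
            raise ValueError(
                f"{a.name}: read 1 shorter than barcode+UMI ({len(a.seq)} < {need})")
        st.total += 1
        bc = a.seq[: spec.barcode_length]
        umi = a.seq[spec.barcode_length : need]
        if spec.whitelist is not None:
            fixed = _correct_barcode(bc, spec.whitelist)
            if fixed is None:
                st.dropped += 1
                continue
            if fixed == bc:
                st.exact += 1
            else:
                st.corrected += 1
                bc = fixed
        else:
            st.exact += 1
        yield FastqRecord(f"{b.name}_CB:{bc}_UMI:{umi}", b.seq, b.qual)


def parse_cb_umi(name: str) -> tuple[str, str] | None:
    """Extract the (barcode, UMI) tokens from an annotated read name."""
    cb = umi = None
    for tok in name.split("_"):
        if tok.startswith("CB:"):
            cb = tok[3:]
        elif tok.startswith("UMI:"):
            umi = tok[4:]
    return (cb, umi) if cb is not None and umi is not None else None


@dataclass
class CountMatrix:
    """Sparse UMI-deduplicated counts with barcode and feature vocabularies."""

    barcodes: list[str]
    gene_ids: list[str]
    counts: dict[tuple[int, int], int]
    normalized: dict[tuple[int, int], float] | None = None

    def count(self, barcode: str, gene_id: str) -> int:
        try:
            key = (self.barcodes.index(barcode), self.gene_ids.index(gene_id))
        except ValueError:
            return 0
        return self.counts.get(key, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict[tuple[str, str], int]:
        return {
            (self.barcodes[ci], self.gene_ids[gi]): n
            for (ci, gi), n in self.counts.items()
        }

    def write(self, prefix: str) -> None:
        """Write the conventional triplet layout: matrix.mtx + barcodes.tsv
        + features.tsv (MatrixMarket coordinate, 1-based indices)."""
        with open(prefix + "barcodes.tsv", "w") as f:
            f.writelines(b + "\n" for b in self.barcodes)
        with open(prefix + "features.tsv", "w") as f:
            f.writelines(g + "\n" for g in self.gene_ids)
        entries = sorted(self.counts.items())
        with open(prefix + "matrix.mtx", "w") as f:
            f.write("%%MatrixMarket matrix coordinate integer general\n")
            f.write(f"{len(self.gene_ids)} {len(self.barcodes)} {len(entries)}\n")
            for (ci, gi), n in entries:
                f.write(f"{gi + 1} {ci + 1} {n}\n")


@dataclass
class CountAudit:
    primary_mapped: int = 0
    assigned: int = 0
    ambiguous: int = 0
    intergenic: int = 0
    dropped: int = 0  # missing/filtered barcode or UMI
    duplicate_umis: int = 0  # assigned reads collapsed away by UMI dedup


def sc_count(sam_records: Iterable[SamRecord], genes: list[GeneModel],
             whitelist: Iterable[str] | None = None,
             input_counts: dict[str, float] | None = None,
             stranded: bool = False, skip_missing: bool = False,
             audit: CountAudit | None = None) -> CountMatrix:
    """UMI-deduplicated (cell, gene) count matrix from annotated alignments.

    A primary mapped read is assigned to a gene iff its alignment interval
    overlaps that gene's exons and no other gene's (ambiguous and
    intergenic reads are counted and discarded).  With ``input_counts``
    (per-gene totals from an input/control library), a parallel normalized
    matrix holds count / (input_counts[gene] + 1).
    """
    aud = audit if audit is not None else CountAudit()
    wl = frozenset(whitelist) if whitelist is not None else None

    exon_index = IntervalIndex()
    for g in genes:
        for exon in g.exons:
            exon_index.add(_Exon(g, exon))

    molecules: dict[tuple[str, str], set[str]] = {}
    for rec in sam_records:
        if rec.is_unmapped or not rec.is_primary:
            continue
        aud.primary_mapped += 1
        tokens = parse_cb_umi(rec.qname)
        if tokens is None:
            if skip_missing:
                aud.dropped += 1
                continue
            raise ValueError(f"read {rec.qname!r} lacks CB/UMI tokens")
        cb, umi = tokens
        if wl is not None and cb not in wl:
            aud.dropped += 1
            continue
        hits = exon_index.query(rec.rname, rec.start, rec.end)
        if stranded:
            strand = "-" if rec.is_reverse else "+"
            hits = [h for h in hits if h.gene.strand == strand]
        hit_genes = {h.gene.gene_id for h in hits}
        if not hit_genes:
            aud.intergenic += 1
            continue
        if len(hit_genes) > 1:
            aud.ambiguous += 1
            continue
        gene_id = next(iter(hit_genes))
        aud.assigned += 1
        umis = molecules.setdefault((cb, gene_id), set())
        if umi in umis:
            aud.duplicate_umis += 1
        else:
            umis.add(umi)

    barcodes = sorted({cb for cb, _ in molecules})
    gene_ids = [g.gene_id for g in genes]
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    g_idx = {g: i for i, g in enumerate(gene_ids)}
    counts = {
        (bc_idx[cb], g_idx[gid]): len(umis)
        for (cb, gid), umis in molecules.items()
    }
    normalized = None
    if input_counts is not None:
        normalized = {
            (ci, gi): n / (input_counts.get(gene_ids[gi], 0.0) + 1.0)
            for (ci, gi), n in counts.items()
        }
    return CountMatrix(barcodes, gene_ids, counts, normalized)


@dataclass
class _Exon:
    gene: GeneModel
    interval: object
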