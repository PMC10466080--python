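"""Illumina-style read simulation and fixture generators with retained truth.

Every generator is deterministic under a fixed seed and records the exact
ground truth beside its output — per-read origins, per-chain base-level
coordinate maps, per-read (cell, gene, UMI) designs — so downstream
modules can be verified exactly rather than statistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats.chain import ChainAlignment
from .formats.fastq import FastqRecord
from .formats.gtf import GeneModel
from .formats.sam import (FLAG_FIRST, FLAG_MATE_REVERSE, FLAG_MATE_UNMAPPED,
                          FLAG_PAIRED, FLAG_PROPER_PAIR, FLAG_REVERSE,
                          FLAG_SECOND, SamRecord)
from .seqcore import Sequence, reverse_complement
from .singlecell import BarcodeSpec

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimConfig:
    n_reads: int
    read_length: int = 100
    error_rate: float = 0.0
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be >= 1")


@dataclass
class ReadTruth:
    name: str
    chrom: str
    start: int
    strand: str


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    if not hit.any():
        return seq
    for i in np.flatnonzero(hit):
        alternatives = [b for b in "ACGT" if b != arr[i].upper()]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


def simulate_sam(ref: dict[str, Sequence], cfg: ReadSimConfig,
                 ) -> tuple[list[SamRecord], list[ReadTruth]]:
    """Simulate uniformly-placed error-bearing reads with ``<L>M`` CIGARs.

    Start positions are uniform over the valid starts of all contigs long
    enough to hold a read (shorter contigs are excluded; all excluded is
    an error); strand is uniform; each base substitutes with probability
    ``error_rate``, uniformly over the three alternatives.  Paired mode
    draws the insert from a normal truncated at the read length and emits
    FR proper pairs.  The truth list records every read's true origin.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    qual = chr(cfg.base_quality + 33) * L
    contigs = [(name, s.seq) for name, s in ref.items() if len(s.seq) >= L]
    if not contigs:
        raise ValueError(f"no contig is at least {L} bases long")

    records: list[SamRecord] = []
    truth: list[ReadTruth] = []

    if not cfg.paired:
        weights = np.array([len(s) - L + 1 for _, s in contigs], dtype=float)
        weights /= weights.sum()
        for i in range(cfg.n_reads):
            ci = rng.choice(len(contigs), p=weights)
            name, seq = contigs[ci]
            start = int(rng.integers(0, len(seq) - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            frag = seq[start : start + L].upper()
            read = frag if strand == "+" else reverse_complement(frag)
            read = _apply_errors(read, cfg.error_rate, rng)
            stored = read if strand == "+" else reverse_complement(read)
            qname = f"read_{i}"
            records.append(SamRecord(
                qname=qname, flag=0 if strand == "+" else FLAG_REVERSE,
                rname=name, pos=start, mapq=60, cigar=[(L, "M")],
                seq=stored, qual=qual,
            ))
            truth.append(ReadTruth(qname, name, start, strand))
        return records, truth

    for i in range(cfg.n_reads):
        insert = max(L, int(round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
        eligible = [(n, s) for n, s in contigs if len(s) >= insert]
        if not eligible:
            eligible = contigs
            insert = L
        weights = np.array([len(s) - insert + 1 for _, s in eligible], dtype=float)
        weights /= weights.sum()
        ci = rng.choice(len(eligible), p=weights)
        name, seq = eligible[ci]
        start = int(rng.integers(0, len(seq) - insert + 1))
        mate_start = start + insert - L
        r1_fwd = rng.random() < 0.5
        qname = f"frag_{i}"
        f1 = seq[start : start + L].upper()
        f2 = reverse_complement(seq[mate_start : mate_start + L].upper())
        f1 = _apply_errors(f1, cfg.error_rate, rng)
        f2 = _apply_errors(f2, cfg.error_rate, rng)
        base = FLAG_PAIRED | FLAG_PROPER_PAIR
        first_extra = FLAG_FIRST if r1_fwd else FLAG_SECOND
        second_extra = FLAG_SECOND if r1_fwd else FLAG_FIRST
        records.append(SamRecord(
            qname=qname, flag=base | FLAG_MATE_REVERSE | first_extra,
            rname=name, pos=start, mapq=60, cigar=[(L, "M")], rnext="=",
            pnext=mate_start, tlen=insert, seq=f1, qual=qual,
        ))
        records.append(SamRecord(
            qname=qname, flag=base | FLAG_REVERSE | second_extra,
            rname=name, pos=mate_start, mapq=60, cigar=[(L, "M")], rnext="=",
            pnext=start, tlen=-insert,
            seq=reverse_complement(f2), qual=qual,
        ))
        truth.append(ReadTruth(qname, name, start, "+"))
        truth.append(ReadTruth(qname, name, mate_start, "-"))
    return records, truth


# ---------------------------------------------------------------------------
# assembly pairs and chains
# ---------------------------------------------------------------------------

@dataclass
class AssemblyTruth:
    """Per-base target->query map: position arrays (-1 unmapped) and strand
    arrays (+1 forward, -1 inverted)."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)


def make_assembly_pair(ref: dict[str, Sequence], n_rearrangements: int,
                       seed: int, size_range: tuple[int, int] = (5, 50),
                       ) -> tuple[dict[str, Sequence], list[ChainAlignment], AssemblyTruth]:
    """Derive a rearranged assembly plus the chains and true coordinate map.

    Random deletions, insertions and inversions (sizes uniform in
    ``size_range``) are applied per chromosome; colinear runs become one
    ``+`` strand chain with dt/dq gaps, each inversion becomes its own
    ``-`` strand chain.  All emitted chains satisfy the block-arithmetic
    invariants by construction (validated).
    """
    rng = np.random.default_rng(seed)
    derived: dict[str, Sequence] = {}
    chains: list[ChainAlignment] = []
    truth = AssemblyTruth()
    chain_id = 1

    names = list(ref)
    ops_per_chrom = {n: [] for n in names}
    for k in range(n_rearrangements):
        ops_per_chrom[names[int(rng.integers(len(names)))]].append(k)

    for name in names:
        seq = ref[name].seq
        n_ops = len(ops_per_chrom[name])
        ops = _sample_ops(len(seq), n_ops, size_range, rng)
        d_seq_parts: list[str] = []
        pos_map = np.full(len(seq), -1, dtype=np.int64)
        strand_map = np.ones(len(seq), dtype=np.int64)
        # segments: (kind, ref_a, ref_b, derived_a) with kind in {fwd, inv}
        segments: list[tuple[str, int, int, int]] = []
        cur = 0
        d_pos = 0
        for kind, a, b, ins_len in ops:
            if a > cur:
                segments.append(("fwd", cur, a, d_pos))
                d_seq_parts.append(seq[cur:a])
                pos_map[cur:a] = np.arange(d_pos, d_pos + (a - cur))
                d_pos += a - cur
            if kind == "del":
                pass
            elif kind == "inv":
                segments.append(("inv", a, b, d_pos))
                d_seq_parts.append(reverse_complement(seq[a:b]))
                pos_map[a:b] = np.arange(d_pos + (b - a) - 1, d_pos - 1, -1)
                strand_map[a:b] = -1
                d_pos += b - a
            else:  # insertion of novel sequence at a (b == a)
                ins = "".join(_BASES[rng.integers(0, 4, size=ins_len)])
                d_seq_parts.append(ins)
                d_pos += ins_len
            cur = b
        if cur < len(seq):
            segments.append(("fwd", cur, len(seq), d_pos))
            d_seq_parts.append(seq[cur:])
            pos_map[cur:] = np.arange(d_pos, d_pos + (len(seq) - cur))
            d_pos += len(seq) - cur
        d_seq = "".join(d_seq_parts)
        derived[name] = Sequence(name, d_seq)
        truth.positions[name] = pos_map
        truth.strands[name] = strand_map
        q_size = len(d_seq)
        t_size = len(seq)

        # one '+' chain over all forward segments
        fwd = [s for s in segments if s[0] == "fwd"]
        if fwd:
            blocks: list[tuple[int, int | None, int | None]] = []
            for i, (_, a, b, d) in enumerate(fwd):
                if i + 1 < len(fwd):
                    _, a2, _, d2 = fwd[i + 1]
                    blocks.append((b - a, a2 - b, d2 - (d + (b - a))))
                else:
                    blocks.append((b - a, None, None))
            c = ChainAlignment(
                score=sum(b - a for _, a, b, _ in fwd),
                t_name=name, t_size=t_size, t_strand="+",
                t_start=fwd[0][1], t_end=fwd[-1][2],
                q_name=name, q_size=q_size, q_strand="+",
                q_start=fwd[0][3],
                q_end=fwd[-1][3] + (fwd[-1][2] - fwd[-1][1]),
                chain_id=chain_id, blocks=blocks,
            )
            c.validate()
            chains.append(c)
            chain_id += 1
        # one '-' chain per inversion
        for _, a, b, d in (s for s in segments if s[0] == "inv"):
            size = b - a
            c = ChainAlignment(
                score=size, t_name=name, t_size=t_size, t_strand="+",
                t_start=a, t_end=b, q_name=name, q_size=q_size,
                q_strand="-", q_start=q_size - (d + size), q_end=q_size - d,
                chain_id=chain_id, blocks=[(size, None, None)],
            )
            c.validate()
            chains.append(c)
            chain_id += 1
    return derived, chains, truth


def _sample_ops(chrom_len: int, n_ops: int, size_range: tuple[int, int],
                rng: np.random.Generator) -> list[tuple[str, int, int, int]]:
    """Non-overlapping rearrangement ops as (kind, ref_a, ref_b, ins_len)."""
    lo, hi = size_range
    ops: list[tuple[str, int, int, int]] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(ops) < n_ops and attempts < n_ops * 200:
        attempts += 1
        kind = ("del", "ins", "inv")[int(rng.integers(3))]
        size = int(rng.integers(lo, hi + 1))
        if kind == "ins":
            a = int(rng.integers(0, chrom_len + 1))
            span = (a, a + 1)
            b, ins_len = a, size
        else:
            if chrom_len <= size:
                continue
            a = int(rng.integers(0, chrom_len - size + 1))
            span = (a, a + size)
            b, ins_len = a + size, 0
        # keep one base of spacing so segments stay well-formed
        if any(span[0] < e + 1 and s < span[1] + 1 for s, e in taken):
            continue
        taken.append(span)
        ops.append((kind, a, b, ins_len))
    ops.sort(key=lambda o: o[1])
    return ops


# ---------------------------------------------------------------------------
# barcoded single-cell fixtures
# ---------------------------------------------------------------------------

@dataclass
class BarcodedDesign:
    cell: str
    gene_id: str
    n_umis: int
    reads_per_umi: int


def _random_umi(length: int, rng: np.random.Generator, used: set[str]) -> str:
    while True:
        u = "".join(_BASES[rng.integers(0, 4, size=length)])
        if u not in used:
            used.add(u)
            return u


def simulate_barcoded_reads(ref: dict[str, Sequence], genes: list[GeneModel],
                            design: list[BarcodedDesign], seed: int,
                            spec: BarcodeSpec | None = None,
                            read_length: int = 90,
                            ) -> tuple[list[FastqRecord], list[FastqRecord],
                                       dict[tuple[str, str], int]]:
    """10x-style paired FASTQ from a (cell, gene, UMI) design.

    R1 is barcode+UMI padded with A to a fixed carrier length; R2 is
    exonic sequence of the designated gene.  The returned truth is the
    expected UMI-deduplicated count matrix {(cell, gene): n_umis}.
    """
    spec = spec or BarcodeSpec()
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    truth: dict[tuple[str, str], int] = {}
    used_umis: set[str] = set()
    n = 0
    for d in design:
        gene = by_id[d.gene_id]
        if not gene.exons:
            raise ValueError(f"gene {d.gene_id!r} has no exons")
        truth[(d.cell, d.gene_id)] = truth.get((d.cell, d.gene_id), 0) + d.n_umis
        for _ in range(d.n_umis):
            umi = _random_umi(spec.umi_length, rng, used_umis)
            exon = gene.exons[int(rng.integers(len(gene.exons)))]
            length = min(read_length, exon.end - exon.start)
            start = exon.start + int(rng.integers(0, exon.end - exon.start - length + 1))
            cdna = ref[gene.chrom].seq[start : start + length].upper()
            for _ in range(d.reads_per_umi):
                name = f"sc_{n}"
                n += 1
                carrier = d.cell + umi
                r1.append(FastqRecord(name + "/1", carrier, "I" * len(carrier)))
                r2.append(FastqRecord(name + "/2", cdna, "I" * len(cdna)))
    return r1, r2, truth


def simulate_barcoded_sam(ref: dict[str, Sequence], genes: list[GeneModel],
                          design: list[BarcodedDesign], seed: int,
                          spec: BarcodeSpec | None = None,
                          read_length: int = 90,
                          ) -> tuple[list[SamRecord], dict[tuple[str, str], int]]:
    """Aligned counterpart of :func:`simulate_barcoded_reads`.

    Reads carry CB/UMI name tokens and align within single exons of their
    designated gene, so the expected count matrix is exactly the design.
    """
    spec = spec or BarcodeSpec()
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    records: list[SamRecord] = []
    truth: dict[tuple[str, str], int] = {}
    used_umis: set[str] = set()
    n = 0
    for d in design:
        gene = by_id[d.gene_id]
        if not gene.exons:
            raise ValueError(f"gene {d.gene_id!r} has no exons")
        truth[(d.cell, d.gene_id)] = truth.get((d.cell, d.gene_id), 0) + d.n_umis
        for _ in range(d.n_umis):
            umi = _random_umi(spec.umi_length, rng, used_umis)
            exon = gene.exons[int(rng.integers(len(gene.exons)))]
            length = min(read_length, exon.end - exon.start)
            start = exon.start + int(rng.integers(0, exon.end - exon.start - length + 1))
            seq = ref[gene.chrom].seq[start : start + length].upper()
            for _ in range(d.reads_per_umi):
                qname = f"sc_{n}_CB:{d.cell}_UMI:{umi}"
                n += 1
                records.append(SamRecord(
                    qname=qname, flag=0, rname=gene.chrom, pos=start,
                    mapq=60, cigar=[(length, "M")], seq=seq,
                    qual="I" * length,
                ))
    return records, truth
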