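"""Record filters: conjunctions of typed predicates over interval-bearing records.

A record passes iff all configured predicates pass; input order is
preserved and filtering is lazy.  VCF criteria add allele-frequency,
variant-class, per-sample-genotype and INFO-field predicates.  The allele
frequency is computed from the GT fields (alt alleles / called alleles),
not the INFO AF key, unless an INFO predicate names AF explicitly.
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .vcf import VcfRecord

_OPS = {
    "<": operator.lt, "<=": operator.le, ">": operator.gt,
    ">=": operator.ge, "=": operator.eq, "==": operator.eq,
}


@dataclass
class Criteria:
    """Interval-level predicates applicable to any format."""

    min_len: int | None = None
    max_len: int | None = None
    chroms: set[str] | None = None
    name_pattern: str | None = None

    def passes(self, record) -> bool:
        length = record.end - record.start
        if self.min_len is not None and length < self.min_len:
            return False
        if self.max_len is not None and length > self.max_len:
            return False
        if self.chroms is not None and record.chrom not in self.chroms:
            return False
        if self.name_pattern is not None:
            name = getattr(record, "name", None) or getattr(record, "id", None) or ""
            if not re.search(self.name_pattern, name):
                return False
        return True


@dataclass
class VcfCriteria(Criteria):
    af_min: float | None = None
    af_max: float | None = None
    variant_class: str | None = None  # snv | indel | multiallelic
    sample_genotype: tuple[str, str] | None = None  # (sample name, "0/1"-style GT)
    info: list[tuple[str, str, str]] = field(default_factory=list)  # (key, op, value)

    def passes(self, record: VcfRecord, samples: list[str] | None = None) -> bool:  # type: ignore[override]
        if not super().passes(record):
            return False
        if self.af_min is not None or self.af_max is not None:
            af = record.allele_frequency()
            if af is None:
                return False
            if self.af_min is not None and af < self.af_min:
                return False
            if self.af_max is not None and af > self.af_max:
                return False
        if self.variant_class is not None:
            ok = {
                "snv": record.is_snv,
                "indel": record.is_indel,
                "multiallelic": record.is_multiallelic,
            }.get(self.variant_class)
            if ok is None:
                raise ValueError(f"unknown variant class {self.variant_class!r}")
            if not ok:
                return False
        if self.sample_genotype is not None:
            sample, want = self.sample_genotype
            if samples is None or sample not in samples:
                raise ValueError(f"sample {sample!r} absent from VCF header")
            idx = samples.index(sample)
            gts = record.genotypes()
            if idx >= len(gts):
                return False
            got = gts[idx]
            want_alleles = tuple(
                None if t == "." else int(t)
                for t in want.replace("|", "/").split("/")
            )
            if sorted(got.alleles, key=lambda a: (a is None, a)) != sorted(
                    want_alleles, key=lambda a: (a is None, a)):
                return False
        for key, op, value in self.info:
            if op not in _OPS:
                raise ValueError(f"unknown INFO operator {op!r}")
            if key not in record.info:
                return False  # records lacking a tested key fail that predicate
            got = record.info[key]
            if got is None:
                return False
            try:
                ok = _OPS[op](float(got), float(value))
            except ValueError:
                if op not in ("=", "=="):
                    return False
                ok = got == value
            if not ok:
                return False
        return True


def filter_records(records: Iterable, criteria: Criteria,
                   samples: list[str] | None = None) -> Iterator:
    """Lazily yield records passing all predicates, preserving input order."""
    if isinstance(criteria, VcfCriteria):
        for r in records:
            if criteria.passes(r, samples):
                yield r
    else:
        for r in records:
            if criteria.passes(r):
                yield r
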