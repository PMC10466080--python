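"""Overlap enrichment/depletion statistics between two interval sets.

Null model: each A element is placed independently and uniformly at
random (length preserved) over the valid start positions of the search
space, with B held fixed.  The number of A elements overlapping B is then
a sum of independent, non-identical Bernoulli trials — a Poisson-binomial
variable — whose tail can be computed exactly, approximated by a
continuity-corrected Gaussian, or estimated by Monte-Carlo permutation.
Overlap is counted element-wise: an A element either hits B or it does
not, regardless of how many bases overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _clip_merged(merged: Sequence[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    return [(max(s, lo), min(e, hi)) for s, e in merged if min(e, hi) > max(s, lo)]


@dataclass
class _Chrom:
    """Per-chromosome placement geometry for one search space window set."""

    size: int
    windows: list[tuple[int, int]]  # disjoint sorted regions where starts may fall
    b_merged: list[tuple[int, int]]


class NullModel:
    """Uniform-placement null: precomputed per-length hit probabilities."""

    def __init__(self, b_by_chrom: dict[str, list[tuple[int, int]]],
                 chrom_sizes: dict[str, int],
                 search_space: dict[str, list[tuple[int, int]]] | None = None):
        self._chroms: dict[str, _Chrom] = {}
        for chrom, size in chrom_sizes.items():
            windows = (search_space.get(chrom, []) if search_space is not None
                       else [(0, size)])
            self._chroms[chrom] = _Chrom(
                size=size,
                windows=merge_intervals(_clip_merged(windows, 0, size)),
                b_merged=merge_intervals(b_by_chrom.get(chrom, [])),
            )
        self._cache: dict[int, float] = {}

    def _per_chrom(self, length: int):
        """(valid starts, hitting starts) per chromosome for a length-ℓ element."""
        for c in self._chroms.values():
            # valid starts s keep [s, s+ℓ) inside the window
            valid = 0
            hits = 0
            # dilate B left by ℓ-1: start s hits iff s in [b_start-ℓ+1, b_end)
            dilated = merge_intervals(
                (s - length + 1, e) for s, e in c.b_merged
            )
            for ws, we in c.windows:
                hi = we - length  # last valid start (inclusive)
                if hi < ws:
                    continue
                valid += hi - ws + 1
                for ds, de in dilated:
                    a, b = max(ds, ws), min(de, hi + 1)
                    if a < b:
                        hits += b - a
            yield c, valid, hits

    def hit_probability(self, length: int) -> float:
        """P(a uniformly placed length-ℓ element overlaps ≥1 base of B)."""
        if length < 1:
            raise ValueError("element length must be >= 1")
        p = self._cache.get(length)
        if p is not None:
            return p
        valid = hits = 0
        for _, v, h in self._per_chrom(length):
            valid += v
            hits += h
        if valid == 0:
            raise ValueError(f"no chromosome can hold an element of length {length}")
        p = hits / valid
        self._cache[length] = p
        return p

    def sample_placements(self, lengths: np.ndarray, n_perms: int,
                          rng: np.random.Generator) -> np.ndarray:
        """Overlap counts k* from ``n_perms`` random placements of all elements."""
        # enumerate valid (chrom, window, offset) starts once per distinct length
        counts = np.zeros(n_perms, dtype=np.int64)
        by_len: dict[int, np.ndarray] = {}
        for length in np.unique(lengths):
            length = int(length)
            starts_hit: list[np.ndarray] = []
            totals: list[int] = []
            chunks = []
            for c, valid, _ in self._per_chrom(length):
                if valid == 0:
                    continue
                dilated = merge_intervals(
                    (s - length + 1, e) for s, e in c.b_merged)
                chunks.append((c, dilated))
                totals.append(valid)
            total = sum(totals)
            if total == 0:
                raise ValueError(f"no valid start for element of length {length}")
            n_here = int(np.sum(lengths == length)) * n_perms
            draws = rng.integers(0, total, size=n_here)
            hit = np.zeros(n_here, dtype=bool)
            offset = 0
            for (c, dilated), valid in zip(chunks, totals):
                sel = (draws >= offset) & (draws < offset + valid)
                if sel.any():
                    local = draws[sel] - offset
                    # map flat index to a start coordinate within the windows
                    starts = np.empty(local.shape, dtype=np.int64)
                    base = 0
                    for ws, we in c.windows:
                        hi = we - length
                        if hi < ws:
                            continue
                        n_w = hi - ws + 1
                        in_w = (local >= base) & (local < base + n_w)
                        starts[in_w] = ws + (local[in_w] - base)
                        base += n_w
                    h = np.zeros(local.shape, dtype=bool)
                    for ds, de in dilated:
                        h |= (starts >= ds) & (starts < de)
                    hit[sel] = h
                offset += valid
            by_len[length] = hit
        # fold per-element hit vectors into per-permutation counts
        for length in np.unique(lengths):
            length = int(length)
            n_el = int(np.sum(lengths == length))
            counts += by_len[length].reshape(n_el, n_perms).sum(axis=0)
        return counts


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) via convolution."""
    p = np.asarray(probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def poisson_binomial_tail(probs: Sequence[float], k: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) for the Poisson-binomial count X."""
    n = len(probs)
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    pmf = poisson_binomial_pmf(probs)
    return float(pmf[k:].sum()), float(pmf[: k + 1].sum())


@dataclass
class EnrichmentReport:
    n_a: int
    observed: int
    expected: float
    enrichment: float
    p_upper: float  # P(X >= observed)
    p_lower: float  # P(X <= observed)
    method: str
    n_perms: int | None = None
    seed: int | None = None


def _to_tuples(records: Iterable) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        iv = getattr(r, "interval", r)
        if iv is None:
            continue
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return out


def overlap_enrichment(a_records: Sequence, b_records: Sequence,
                       chrom_sizes: dict[str, int], method: str = "exact",
                       n_perms: int = 10_000, seed: int = 0,
                       search_space: Sequence | None = None) -> EnrichmentReport:
    """Element-wise overlap enrichment of A in B with an exact, normal or
    permutation p-value.  Deterministic given ``seed``."""
    if method not in ("exact", "normal", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    a_by_chrom = _to_tuples(a_records)
    b_by_chrom = _to_tuples(b_records)
    if not a_by_chrom or not b_by_chrom:
        raise ValueError("A and B must both be non-empty")
    for name, sets in (("A", a_by_chrom), ("B", b_by_chrom)):
        missing = set(sets) - set(chrom_sizes)
        if missing:
            raise ValueError(f"chromosome(s) {sorted(missing)} in {name} absent "
                             f"from chrom.sizes")
    ss = _to_tuples(search_space) if search_space is not None else None
    null = NullModel(b_by_chrom, chrom_sizes, ss)

    b_merged = {c: merge_intervals(ivs) for c, ivs in b_by_chrom.items()}

    def hits_b(chrom: str, s: int, e: int) -> bool:
        for bs, be in b_merged.get(chrom, []):
            if bs >= e:
                break
            if s < be and bs < e:
                return True
        return False

    lengths: list[int] = []
    k = 0
    for chrom in sorted(a_by_chrom):
        for s, e in a_by_chrom[chrom]:
            lengths.append(max(e - s, 1))
            if hits_b(chrom, s, e):
                k += 1
    probs = np.array([null.hit_probability(l) for l in lengths])
    expected = float(probs.sum())
    n_a = len(lengths)
    enr = k / expected if expected > 0 else float("inf")

    if method == "exact":
        p_upper, p_lower = poisson_binomial_tail(probs, k)
        return EnrichmentReport(n_a, k, expected, enr, p_upper, p_lower, "exact")
    if method == "normal":
        var = float((probs * (1.0 - probs)).sum())
        sd = max(np.sqrt(var), 1e-300)
        p_upper = float(stats.norm.sf(k - 0.5, loc=expected, scale=sd))
        p_lower = float(stats.norm.cdf(k + 0.5, loc=expected, scale=sd))
        return EnrichmentReport(n_a, k, expected, enr, p_upper, p_lower, "normal")
    rng = np.random.default_rng(seed)
    perm_counts = null.sample_placements(np.array(lengths), n_perms, rng)
    p_upper = (1 + int((perm_counts >= k).sum())) / (n_perms + 1)
    p_lower = (1 + int((perm_counts <= k).sum())) / (n_perms + 1)
    return EnrichmentReport(n_a, k, expected, enr, p_upper, p_lower,
                            "permutation", n_perms=n_perms, seed=seed)
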