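"""Allele frequency spectra and selection-driven variant simulation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..formats.vcf import VcfRecord
from .selection import DEFAULT_GRID, frequency_grid, stationary_weights


@dataclass
class AlleleFrequencySpectrum:
    """Counts of segregating variants by derived-allele count 1..n-1."""

    n_chromosomes: int
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    folded: bool = False
    n_skipped: int = 0

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros(self.n_chromosomes - 1, dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (self.n_chromosomes - 1,):
                raise ValueError(
                    f"counts must have length {self.n_chromosomes - 1}")

    def __getitem__(self, j: int) -> int:
        """Count of variants with derived-allele count j (1-based bins)."""
        if not 1 <= j <= self.n_chromosomes - 1:
            raise IndexError(f"derived count {j} out of range")
        return int(self.counts[j - 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fold(self) -> "AlleleFrequencySpectrum":
        """Fold bins j and n-j together (minor-allele spectrum)."""
        if self.folded:
            return self
        n = self.n_chromosomes
        folded = np.zeros(n - 1, dtype=np.int64)
        for j in range(1, n):
            folded[min(j, n - j) - 1] += self.counts[j - 1]
        return AlleleFrequencySpectrum(n, folded, folded=True,
                                       n_skipped=self.n_skipped)


def compute_afs(records, polarized: bool = True) -> AlleleFrequencySpectrum:
    """Tally the spectrum from VCF records.

    Only biallelic SNVs with fully-called genotypes are used (others are
    skipped and counted); polarized mode assumes ALT is the derived
    allele, unpolarized mode folds the spectrum.
    """
    afs: AlleleFrequencySpectrum | None = None
    skipped = 0
    for rec in records:
        if not rec.is_snv:
            skipped += 1
            continue
        gts = rec.genotypes()
        if not gts:
            skipped += 1
            continue
        alleles = [a for g in gts for a in g.alleles]
        if any(a is None for a in alleles):
            skipped += 1
            continue
        n = len(alleles)
        if afs is None:
            afs = AlleleFrequencySpectrum(n)
        elif afs.n_chromosomes != n:
            raise ValueError(
                f"inconsistent sample count: {n} chromosomes at "
                f"{rec.chrom}:{rec.start + 1}, expected {afs.n_chromosomes}")
        derived = sum(alleles)
        if 0 < derived < n:
            afs.counts[derived - 1] += 1
        else:
            skipped += 1  # non-segregating
    if afs is None or afs.total == 0:
        raise ValueError("no usable biallelic SNVs with complete genotypes")
    afs.n_skipped = skipped
    return afs.fold() if not polarized else afs


def sample_derived_counts(n_variants: int, n_chrom: int, alpha: float,
                          rng: np.random.Generator,
                          grid_size: int = DEFAULT_GRID) -> np.ndarray:
    """Derived-allele counts for segregating variants under selection.

    Per variant a population frequency x is drawn from the stationary
    grid density and the sample count from Binomial(n, x), conditioned on
    segregating (0 < count < n) by rejection.
    """
    x = frequency_grid(grid_size)
    w = stationary_weights(alpha, grid_size)
    out = np.empty(n_variants, dtype=np.int64)
    need = np.arange(n_variants)
    while need.size:
        freqs = x[rng.choice(grid_size, size=need.size, p=w)]
        draws = rng.binomial(n_chrom, freqs)
        ok = (draws > 0) & (draws < n_chrom)
        out[need[ok]] = draws[ok]
        need = need[~ok]
    return out


def simulate_vcf(n_variants: int, n_samples: int, alpha: float, seed: int,
                 grid_size: int = DEFAULT_GRID,
                 chrom: str = "chrSim") -> tuple[list[VcfRecord], AlleleFrequencySpectrum]:
    """Simulate segregating variants under selection as diploid VCF records.

    Derived counts are drawn from the stationary density (see
    :func:`sample_derived_counts`) and assigned to 2*n_samples chromosome
    slots by random pairing.  Positions are sequential on a synthetic
    contig.  Returns the records and the generator's own spectrum tally,
    so downstream spectrum code can be checked exactly.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if abs(alpha) > 100:
        raise ValueError("|alpha| must be <= 100")
    rng = np.random.default_rng(seed)
    n_chrom = 2 * n_samples
    counts = sample_derived_counts(n_variants, n_chrom, alpha, rng, grid_size)
    truth = AlleleFrequencySpectrum(n_chrom)
    records = []
    for i, j in enumerate(counts):
        truth.counts[j - 1] += 1
        slots = np.zeros(n_chrom, dtype=np.int64)
        slots[rng.permutation(n_chrom)[:j]] = 1
        gts = tuple(
            f"{slots[2 * s]}|{slots[2 * s + 1]}" for s in range(n_samples)
        )
        records.append(VcfRecord(
            chrom=chrom, start=i * 10, id=f"sim_{i}", ref="A", alts=("T",),
            qual=".", filter=".", info={}, format=("GT",), samples=gts,
        ))
    return records, truth
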