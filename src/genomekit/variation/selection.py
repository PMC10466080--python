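"""Wright-Fisher stationary density under selection and MCMC inference.

The population-scaled selection coefficient is alpha = 2Ns.  The
stationary density of the derived allele frequency x in (0, 1) is

    f(x; alpha) = (1 - exp(-alpha (1 - x))) / ((1 - exp(-alpha)) x (1 - x))

with the neutral limit f(x; 0) = 1/x.  Closed forms are unavailable after
binomial sampling of n chromosomes, so the density is discretized on a
uniform grid of G points at x_i = (i + 1/2)/G; the sampling distribution
of the derived-allele count j is the grid-integrated binomial mixture,
renormalized over the segregating classes 1..n-1.

Inference is Metropolis-Hastings on alpha with a Gaussian random walk and
a flat prior on a bounded interval; proposals outside the bounds are
rejected (and counted), never an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

DEFAULT_GRID = 1000


def frequency_grid(grid_size: int = DEFAULT_GRID) -> np.ndarray:
    """Grid midpoints x_i = (i + 1/2)/G in (0, 1)."""
    return (np.arange(grid_size) + 0.5) / grid_size


def stationary_weights(alpha: float, grid_size: int = DEFAULT_GRID) -> np.ndarray:
    """Normalized stationary density on the frequency grid."""
    x = frequency_grid(grid_size)
    if alpha == 0.0:
        w = 1.0 / x
    else:
        # expm1 keeps the ratio stable for |alpha| up to ~100
        w = np.expm1(-alpha * (1.0 - x)) / (np.expm1(-alpha) * x * (1.0 - x))
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"stationary density cannot be normalized at alpha={alpha}")
    return w / total


@lru_cache(maxsize=8)
def _binom_matrix(n_chrom: int, grid_size: int) -> np.ndarray:
    """M[j-1, i] = C(n, j) x_i^j (1-x_i)^(n-j) for j = 1..n-1."""
    x = frequency_grid(grid_size)
    j = np.arange(1, n_chrom)[:, None]
    return stats.binom.pmf(j, n_chrom, x[None, :])


def afs_probabilities(alpha: float, n_chrom: int,
                      grid_size: int = DEFAULT_GRID) -> np.ndarray:
    """P(derived count = j | alpha, n) for j = 1..n-1, summing to 1."""
    if n_chrom < 2:
        raise ValueError("need at least 2 sampled chromosomes")
    w = stationary_weights(alpha, grid_size)
    p = _binom_matrix(n_chrom, grid_size) @ w
    return p / p.sum()


def log_likelihood(counts: np.ndarray, alpha: float, n_chrom: int,
                   grid_size: int = DEFAULT_GRID) -> float:
    """Multinomial log-likelihood of spectrum counts[j-1], j = 1..n-1."""
    p = afs_probabilities(alpha, n_chrom, grid_size)
    return float(np.dot(counts, np.log(p)))


@dataclass
class McmcTrace:
    samples: np.ndarray  # post-burn-in alpha draws
    log_likelihoods: np.ndarray
    acceptance_rate: float
    n_out_of_bounds: int
    seed: int
    burn_in: int

    @property
    def posterior_mean(self) -> float:
        return float(self.samples.mean())

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        a, b = np.quantile(self.samples, [lo, 1.0 - lo])
        return float(a), float(b)


def selection_mcmc(counts: np.ndarray, n_chrom: int, iterations: int = 5000,
                   burn_in: int = 1000, proposal_sd: float = 0.5, seed: int = 0,
                   alpha_bounds: tuple[float, float] = (-50.0, 50.0),
                   alpha_init: float = 0.0,
                   grid_size: int = DEFAULT_GRID) -> McmcTrace:
    """Random-walk Metropolis sampling of alpha given an observed spectrum.

    ``counts`` has length n_chrom - 1 (derived counts 1..n-1).  The trace
    holds ``iterations - burn_in`` post-burn-in samples and is fully
    deterministic given ``seed``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (n_chrom - 1,):
        raise ValueError(
            f"counts must have length {n_chrom - 1}, got {counts.shape}")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    lo, hi = alpha_bounds
    if not lo <= alpha_init <= hi:
        raise ValueError("alpha_init outside bounds")
    rng = np.random.default_rng(seed)
    alpha = alpha_init
    ll = log_likelihood(counts, alpha, n_chrom, grid_size)
    samples = np.empty(iterations - burn_in)
    lls = np.empty(iterations - burn_in)
    accepted = 0
    out_of_bounds = 0
    for it in range(iterations):
        prop = alpha + rng.normal(0.0, proposal_sd)
        if lo <= prop <= hi:
            ll_prop = log_likelihood(counts, prop, n_chrom, grid_size)
            if np.log(rng.uniform()) < ll_prop - ll:
                alpha, ll = prop, ll_prop
                accepted += 1
        else:
            out_of_bounds += 1
        if it >= burn_in:
            samples[it - burn_in] = alpha
            lls[it - burn_in] = ll
    return McmcTrace(
        samples=samples, log_likelihoods=lls,
        acceptance_rate=accepted / iterations,
        n_out_of_bounds=out_of_bounds, seed=seed, burn_in=burn_in,
    )
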