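"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here are deliberately naive (per-base scans, exact integer
hypergeometric enumeration) and independent of the library code paths they
check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import pytest

from corepeat.genome import GenomicInterval
from corepeat.simulate import SimConfig, simulate_annotation


def brute_interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Per-base scan: 0 on any shared base, else bases strictly between."""
    if a.chrom != b.chrom:
        return math.inf
    bases_a = set(range(a.start, a.end))
    bases_b = set(range(b.start, b.end))
    if bases_a & bases_b:
        return 0.0
    return float(min(abs(i - j) for i in bases_a for j in bases_b) - 1)


def brute_overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def hypergeom_pmf_exact(N: int, K: int, n: int):
    """Exact hypergeometric pmf over the support, as floats of integer ratios.

    Returns (support array, pmf array), computed purely from binomial
    coefficients with integer arithmetic.
    """
    lo, hi = max(0, n + K - N), min(n, K)
    denom = math.comb(N, n)
    support = list(range(lo, hi + 1))
    pmf = [
        float(Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom))
        for k in support
    ]
    return support, pmf


def enum_fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail p by direct summation of the exact pmf."""
    N, K, n = a + b + c + d, a + c, a + b
    support, pmf = hypergeom_pmf_exact(N, K, n)
    return sum(p for k, p in zip(support, pmf) if k >= a)


def enum_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided p by direct enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    support, pmf = hypergeom_pmf_exact(N, K, n)
    p_obs = pmf[support.index(a)]
    return sum(p for p in pmf if p <= p_obs * (1 + 1e-7))


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, max_pos)))
    return out


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced genome used by tests that do not need the default scale."""
    return SimConfig(
        seed=20_240,
        n_chroms=2,
        chrom_len=2_000_000,
        n_genes=80,
        target_fraction=0.25,
    )


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    bundle, truth = simulate_annotation(small_sim_config)
    return bundle, truth


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale simulated study shared across tests (seed 1)."""
    bundle, truth = simulate_annotation(SimConfig(seed=1))
    return bundle, truth
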