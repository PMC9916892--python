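"""Exact discrete-tail statistics shared across the pipeline.

The Poisson-binomial survival function is the hotspot recurrence null; the
exact hypergeometric tail backs both the per-base case/control CNV test
(one-sided Fisher) and the gene-set over-representation test.  Tails are
computed with exact integer arithmetic where feasible so that results agree
with enumeration to near machine precision.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "poisson_binomial_pmf",
    "poisson_binomial_sf",
    "hypergeom_sf",
    "fisher_exact_case_enrichment",
    "population_skewness_kurtosis",
]


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """PMF of the sum of independent Bernoulli(p_i) trials.

    Computed by iterative convolution (dynamic programming), O(n^2) and
    numerically stable for the cohort sizes used here (hundreds of samples).
    Returns an array of length ``n + 1``.
    """
    p = np.asarray(probs, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("all probabilities must be in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        # after i+1 trials only entries 0..i+1 are populated
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def poisson_binomial_sf(k: int, probs: Sequence[float]) -> float:
    """Tail probability P(K >= k) for K = sum of Bernoulli(p_i).

    ``k <= 0`` returns 1.0 (certain event); ``k > n`` returns 0.0 (impossible
    event, not an error).
    """
    n = len(probs)
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    pmf = poisson_binomial_pmf(probs)
    return float(min(1.0, max(0.0, pmf[k:].sum())))


def hypergeom_sf(x: int, N: int, K: int, n: int) -> float:
    """Exact tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    N = population size, K = success states, n = draws.  The numerator is an
    exact integer sum of C(K, i) * C(N-K, n-i); the single final division is
    the only floating-point step.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if x <= lo:
        return 1.0
    if x > hi:
        return 0.0
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(x, hi + 1))
    return num / math.comb(N, n)


def fisher_exact_case_enrichment(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for enrichment of the first row.

    Table: a = cases covering, b = cases not covering, c/d likewise for
    controls.  Equals the hypergeometric tail P(X >= a) with population
    N = a+b+c+d, success states K = a+b (cases), draws n = a+c (covering).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    N = a + b + c + d
    return hypergeom_sf(a, N, a + b, a + c)


def population_skewness_kurtosis(values: Sequence[float]) -> tuple[float, float]:
    """Population (biased) skewness m3/m2^1.5 and non-excess kurtosis m4/m2^2.

    Raises on fewer than 3 values or zero variance (undefined moments).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    centered = x - x.mean()
    m2 = np.mean(centered**2)
    if m2 == 0.0:
        raise ValueError("moments undefined for constant input")
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)
    return float(m3 / m2**1.5), float(m4 / m2**2)
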