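"""Statistics for allelic-imbalance testing.

The allelic-imbalance test is an exact two-sided binomial test against a
null proportion of 1/2: after realignment to the two personal genomes the
no-bias expectation at a heterozygous site is an even split of reads
between the haplotypes.  Multiple testing across all tested sites is
controlled with the Benjamini-Hochberg step-up (Bonferroni available as an
alternative).
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike
from scipy.stats import binom


def binom_two_sided(k: ArrayLike, n: ArrayLike, p0: float = 0.5):
    """Exact two-sided binomial p-value: min(1, 2*min(P(X<=k), P(X>=k))).

    Doubling the smaller tail is the standard two-sided convention for a
    symmetric null; at p0=0.5 it coincides with summing all outcomes at
    least as extreme.  Vectorized over k and n.

    Parameters
    ----------
    k : observed count for haplotype 1
    n : total informative reads (must be >= 1; a site with n=0 is
        untestable and should be skipped upstream, not passed here)
    """
    k_arr = np.asarray(k, dtype=np.int64)
    n_arr = np.asarray(n, dtype=np.int64)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1 (n=0 sites are untestable, skip them)")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise ValueError("k must satisfy 0 <= k <= n")
    lower = binom.cdf(k_arr, n_arr, p0)
    upper = binom.sf(k_arr - 1, n_arr, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def bh_adjust(p_values: ArrayLike) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in the
    input order.  Empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bonferroni_adjust(p_values: ArrayLike) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size) if p.size else np.empty(0)


def expected_het_fraction(maf_low: float = 0.0, maf_high: float = 0.5) -> float:
    """Mean Hardy-Weinberg heterozygosity 2p(1-p) for MAF uniform on an interval.

    Under HWE a site with minor-allele frequency p is heterozygous in a
    random individual with probability 2p(1-p).  Averaging over p uniform
    on (maf_low, maf_high) gives, in closed form,

        E[2p(1-p)] = (b^2 - a^2 - (2/3)(b^3 - a^3)) / (b - a).

    For common polymorphic sites (p uniform on (0, 0.5)) this is exactly
    1/3: about a third of common variants are heterozygous in one person.
    """
    a, b = float(maf_low), float(maf_high)
    if not 0.0 <= a < b <= 1.0:
        raise ValueError("require 0 <= maf_low < maf_high <= 1")
    return (b**2 - a**2 - (2.0 / 3.0) * (b**3 - a**3)) / (b - a)


def binomial_power_at_threshold(n: int, p_alt: float, p_crit: float, p0: float = 0.5) -> float:
    """Probability that a Binomial(n, p_alt) site yields a two-sided p-value <= p_crit.

    Direct tail summation over all n+1 outcomes; used to predict the
    recovery rate of planted imbalanced sites at a realized BH threshold.
    """
    k = np.arange(n + 1)
    reject = binom_two_sided(k, np.full(n + 1, n), p0) <= p_crit
    return float(binom.pmf(k[reject], n, p_alt).sum())
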