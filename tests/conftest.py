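"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by brute force
(rational hypergeometric sums, complete group-assignment enumeration,
partial Poisson sums, two-pass covariance) so the package's fast paths
are checked against something they do not share code with.
"""
from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from resistaxis.synthetic_data import SynthConfig, make_gene_annotation, make_series
from resistaxis.types import FeatureMatrix, GeneAnnotation, SampleSeries


# --------------------------------------------------------------------------
# oracles


def oracle_covariance(x, c) -> float:
    """Two-pass sample covariance with n-1 denominator."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    xm, cm = x.mean(), c.mean()
    return float(sum((xi - xm) * (ci - cm) for xi, ci in zip(x, c))
                 / (len(x) - 1))


def oracle_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by rational summation over all tables with the
    observed margins and an overlap cell >= a."""
    N, K, n = a + b + c + d, a + c, a + b
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k))
    return float(total / math.comb(N, n))


def oracle_poisson_upper_tail(k: int, lam: float) -> float:
    """P(Poisson(lam) >= k) by direct partial summation in log space.

    Lower-sum complement for k <= lam (tail is large), direct upper sum
    otherwise (tail may be tiny; summing it directly keeps relative
    accuracy).
    """
    if k <= 0:
        return 1.0
    log_lam = math.log(lam)

    def log_pmf(i: int) -> float:
        return -lam + i * log_lam - math.lgamma(i + 1)

    if k <= lam:
        return 1.0 - math.fsum(math.exp(log_pmf(i)) for i in range(k))
    terms = []
    i = k
    while True:
        t = math.exp(log_pmf(i))
        terms.append(t)
        if t < 1e-25 * (terms[0] or 1e-300) or i > k + 10_000:
            break
        i += 1
    return math.fsum(terms)


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Sup-difference of the two ECDFs (tie-safe)."""
    pts = np.concatenate([x, y])
    cdf1 = np.searchsorted(np.sort(x), pts, side="right") / len(x)
    cdf2 = np.searchsorted(np.sort(y), pts, side="right") / len(y)
    return float(np.max(np.abs(cdf1 - cdf2)))


def oracle_ks_exact(x, y) -> tuple[float, float]:
    """Two-sample KS D and exact p by complete group-assignment enumeration.

    Enumerates every way of splitting the pooled values into groups of the
    observed sizes; p is the fraction of assignments with D' >= D_obs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    d_obs = _ks_statistic(x, y)
    count = total = 0
    idx = np.arange(n1 + n2)
    for grp in combinations(idx, n2):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(grp)] = True
        d = _ks_statistic(pooled[~mask], pooled[mask])
        count += d >= d_obs - 1e-12
        total += 1
    return d_obs, count / total


def oracle_ks_alpha_level(n1: int, n2: int, alpha: float = 0.05) -> float:
    """P(exact two-sample KS p < alpha | H0, continuous data).

    The exact test's p-values are discrete, so its true null rejection
    rate at a threshold is the largest achievable level below it, not
    alpha itself. Computed by enumerating the permutation distribution of
    D over all group assignments of distinct pooled ranks.
    """
    n = n1 + n2
    d_values = []
    for grp in combinations(range(n), n2):
        mask = np.zeros(n, dtype=bool)
        mask[list(grp)] = True
        cdf1 = np.cumsum(~mask) / n1
        cdf2 = np.cumsum(mask) / n2
        d_values.append(np.max(np.abs(cdf1 - cdf2)))
    d_values = np.sort(np.array(d_values))
    total = len(d_values)
    # p(D) = fraction of assignments with D' >= D
    p_of = {}
    for d in np.unique(d_values):
        p_of[d] = np.mean(d_values >= d - 1e-12)
    rejected = sum(1 for d in d_values if p_of[d] < alpha)
    return rejected / total


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Scaled-down study: 400 genes, proportional planting, fixed seed."""
    return SynthConfig(
        n_genes=400,
        n_fragments=300,
        n_variants=120,
        n_k1=40,
        n_k2=40,
        n_other=20,
        targets_per_tf=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def series(small_config) -> SampleSeries:
    return make_series(small_config)


@pytest.fixture(scope="session")
def annotation(small_config) -> GeneAnnotation:
    return make_gene_annotation(small_config)


@pytest.fixture()
def toy_series() -> SampleSeries:
    return SampleSeries(
        sample_ids=["P", "A", "B", "C", "D"],
        resistance_rank=np.arange(5),
        ec50=np.array([857.0, 1100.0, 1700.0, 2500.0, 3446.0]),
    )


def feature_matrix(rows: dict, samples, kind="log2_expression") -> FeatureMatrix:
    """Build a FeatureMatrix from {feature: values} for terse tests."""
    return FeatureMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(samples)),
        value_kind=kind,
    )
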