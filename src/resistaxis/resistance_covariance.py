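"""Covariance-with-resistance feature ranking.

Each feature (gene expression, RRBS fragment methylation, or variant allele
frequency) is scored by its sample covariance with a resistance covariate —
the sample's rank in the dose-escalation series, or its EC50. Features are
then ranked and extreme top/bottom lists selected. The covariance (not the
correlation) is used deliberately: amplitude along the series matters, not
just ordering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FeatureMatrix, SampleSeries

__all__ = [
    "CovarianceRanking",
    "covariance_with_resistance",
    "select_extreme_features",
    "vaf_trend_screen",
]


@dataclass
class CovarianceRanking:
    """Per-feature covariances plus selected extreme sets.

    ``table`` is indexed by feature id with columns ``covariance``, ``rank``
    (0 = highest covariance) and ``set_label`` in {top, bottom, ""}.
    """

    table: pd.DataFrame
    size: int

    @property
    def top(self) -> list[str]:
        return list(self.table.index[self.table["set_label"] == "top"])

    @property
    def bottom(self) -> list[str]:
        """Bottom set, most negative covariance first."""
        sub = self.table[self.table["set_label"] == "bottom"]
        return sorted(sub.index, key=lambda f: (sub.at[f, "covariance"],
                                                str(f)))


def covariance_with_resistance(
    matrix: FeatureMatrix,
    series: SampleSeries,
    covariate: str = "rank",
) -> pd.Series:
    """Sample covariance (n-1 denominator) of each feature with the covariate.

    Positive covariance means the feature's value increases with resistance.
    Features with any missing sample value are excluded (NaN-free rows only);
    use :func:`vaf_trend_screen` for pairwise-complete variant handling.

    Raises
    ------
    ValueError
        For fewer than 3 samples or a constant covariate.
    """
    if series.n < 3:
        raise ValueError("need at least 3 samples for a covariance ranking")
    c = series.covariate(covariate)
    if not np.all(np.isfinite(c)):
        raise ValueError("covariate values must be finite")
    if np.ptp(c) == 0:
        raise ValueError("constant covariate: degenerate design")
    values = matrix.aligned_to(series).values
    complete = values.notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"excluding {int((~complete).sum())} features with missing values",
            stacklevel=2,
        )
    x = values.loc[complete].to_numpy(dtype=float)
    cc = c - c.mean()
    cov = (x - x.mean(axis=1, keepdims=True)) @ cc / (len(c) - 1)
    return pd.Series(cov, index=values.index[complete], name="covariance")


def select_extreme_features(
    covariances: pd.Series, size: int = 1000
) -> CovarianceRanking:
    """Select the ``size`` highest- and lowest-covariance features.

    Selection is deterministic: ties are broken by lexicographic feature id.
    When ``size`` exceeds the number of features it is truncated with a
    warning; top and bottom sets may then overlap if n < 2*size.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    n = len(covariances)
    if size > n:
        warnings.warn(f"size {size} > {n} features; truncating", stacklevel=2)
        size = n
    df = pd.DataFrame({"covariance": covariances})
    df = df.loc[sorted(df.index, key=lambda f: (-df.at[f, "covariance"], str(f)))]
    df["rank"] = np.arange(n)
    df["set_label"] = ""
    df.iloc[:size, df.columns.get_loc("set_label")] = "top"
    # bottom: lowest covariance, ties again by id — take from the tail of the
    # same ordering so that top precedence wins on overlap
    bottom_order = sorted(df.index, key=lambda f: (df.at[f, "covariance"], str(f)))
    bottom = bottom_order[:size]
    df.loc[bottom, "set_label"] = np.where(
        df.loc[bottom, "set_label"] == "top", "top", "bottom"
    )
    return CovarianceRanking(table=df, size=size)


def vaf_trend_screen(
    alt_counts: pd.DataFrame,
    ref_counts: pd.DataFrame,
    series: SampleSeries,
    covariance_threshold: float = 0.1,
    covariate: str = "rank",
) -> pd.DataFrame:
    """Screen variants for allele frequencies trending up with resistance.

    VAF = alt/(alt+ref) per cell; zero-depth cells are excluded from the
    per-variant covariance (pairwise-complete over samples). A variant is a
    *candidate* when its covariance with the resistance covariate exceeds
    ``covariance_threshold`` and it has alt reads in at least one sample.
    Variants whose alt reads occur in exactly one sample are flagged
    ``singleton_suspect`` — in serial designs these are frequently alignment
    or sequencing artifacts rather than selected mutations.

    Returns a frame indexed by variant id with columns: covariance,
    n_informative, n_samples_with_alt, candidate, singleton_suspect.
    """
    if not alt_counts.index.equals(ref_counts.index) or list(
        alt_counts.columns
    ) != list(ref_counts.columns):
        raise ValueError("alt and ref count tables must share index and columns")
    alt = alt_counts[series.sample_ids].to_numpy(dtype=float)
    ref = ref_counts[series.sample_ids].to_numpy(dtype=float)
    if (alt < 0).any() or (ref < 0).any():
        raise ValueError("allele counts must be non-negative")
    depth = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.where(depth > 0, depth, 1), np.nan)

    c = series.covariate(covariate)
    dead = ~(depth > 0).any(axis=1)
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} variants with zero depth everywhere",
            stacklevel=2,
        )

    n_inf = (depth > 0).sum(axis=1)
    cov = np.full(len(alt), np.nan)
    for i in range(len(alt)):
        m = depth[i] > 0
        if m.sum() < 2 or np.ptp(c[m]) == 0:
            continue
        ci = c[m] - c[m].mean()
        vi = vaf[i, m] - vaf[i, m].mean()
        cov[i] = (vi @ ci) / (m.sum() - 1)

    n_alt = (alt > 0).sum(axis=1)
    out = pd.DataFrame(
        {
            "covariance": cov,
            "n_informative": n_inf,
            "n_samples_with_alt": n_alt,
            "candidate": (cov > covariance_threshold) & (n_alt >= 1),
            "singleton_suspect": n_alt == 1,
        },
        index=alt_counts.index,
    )
    return out.loc[~dead]
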