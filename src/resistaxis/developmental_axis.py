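"""Projection of cell lines onto a reference developmental expression axis.

Cell-line and reference-atlas expression profiles are decomposed together
by PCA on genes centred and scaled to unit variance (samples are the
observations). The *developmental* component is the one whose reference
scores correlate best (Spearman) with the known stage order; the resistant
lines' scores on that component are then tested for monotonicity in
resistance rank. In the motivating study the developmental signal appears
on the second component, the first separating data sources.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureMatrix, SampleSeries

__all__ = [
    "AtlasProjection",
    "MonotonicityResult",
    "combined_pca",
    "find_developmental_pc",
    "monotonicity_score",
]


@dataclass
class AtlasProjection:
    """Joint PCA of reference and cell-line samples.

    ``scores``: samples x components; ``loadings``: genes x components
    (unit-norm right singular vectors); ``explained_variance_ratio`` is
    non-increasing. ``source`` labels each sample 'reference' or 'line'.
    ``developmental_pc`` (0-based) is set by :func:`find_developmental_pc`.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    source: pd.Series
    n_genes_used: int
    n_genes_dropped: int
    developmental_pc: int | None = None
    stage_correlation: float | None = None

    @property
    def reference_samples(self) -> list[str]:
        return list(self.source.index[self.source == "reference"])

    @property
    def line_samples(self) -> list[str]:
        return list(self.source.index[self.source == "line"])

    def developmental_scores(self) -> pd.Series:
        if self.developmental_pc is None:
            raise ValueError("run find_developmental_pc first")
        return self.scores.iloc[:, self.developmental_pc]


def combined_pca(
    reference: FeatureMatrix, lines: FeatureMatrix
) -> AtlasProjection:
    """PCA of reference and line samples on shared standardized genes.

    Genes are intersected between the two matrices, centred and scaled to
    unit variance (ddof=1) across all samples jointly; zero-variance genes
    are dropped with their count reported. Component signs follow a fixed
    convention: each loading vector's largest-magnitude element is
    positive, so results are reproducible across runs and sample orders.
    """
    shared = reference.values.index.intersection(lines.values.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between reference and lines")
    ref = reference.values.loc[shared]
    lin = lines.values.loc[shared]
    x = pd.concat([ref, lin], axis=1).T  # samples x genes
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples in the combined matrix")

    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        x = x.loc[:, keep]
        sd = sd[keep]
    if x.shape[1] == 0:
        raise ValueError("all genes have zero variance")
    z = (x - x.mean(axis=0)) / sd

    u, s, vt = np.linalg.svd(z.to_numpy(dtype=float), full_matrices=False)
    # fix signs: largest-|.| loading element positive
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    n_comp = len(s)
    pcs = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(u * s, index=x.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=x.columns, columns=pcs)
    evr = s**2 / np.sum(s**2)
    source = pd.Series(
        ["reference"] * ref.shape[1] + ["line"] * lin.shape[1],
        index=list(ref.columns) + list(lin.columns),
        name="source",
    )
    return AtlasProjection(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        source=source,
        n_genes_used=int(keep.sum()),
        n_genes_dropped=n_dropped,
    )


def find_developmental_pc(
    projection: AtlasProjection,
    stage_order: pd.Series,
    correlation_floor: float = 0.5,
) -> int:
    """Identify the component tracking the reference developmental stages.

    ``stage_order`` maps reference sample ids to stage positions (larger =
    more mature). The component with maximal |Spearman| between reference
    scores and stage order wins; ties go to the lowest index with a
    warning. The component is re-oriented in place so that mature stages
    score positive. If the best |correlation| is below
    ``correlation_floor`` a warning flags the axis as unreliable.

    Returns the 0-based component index (also stored on the projection).
    """
    ref = [s for s in projection.reference_samples if s in stage_order.index]
    if len(set(stage_order[ref])) < 2:
        raise ValueError("need at least 2 distinct reference stages")
    stages = stage_order[ref].to_numpy(dtype=float)
    rhos = np.array(
        [
            stats.spearmanr(projection.scores.loc[ref].iloc[:, k], stages)[0]
            for k in range(projection.scores.shape[1])
        ]
    )
    rhos = np.nan_to_num(rhos)
    best = int(np.argmax(np.abs(rhos)))
    ties = np.flatnonzero(np.isclose(np.abs(rhos), np.abs(rhos[best])))
    if len(ties) > 1:
        warnings.warn(
            f"tie in |stage correlation| among components {list(ties)}; "
            "keeping the lowest index",
            stacklevel=2,
        )
        best = int(ties[0])
    if abs(rhos[best]) < correlation_floor:
        warnings.warn(
            f"best |stage correlation| {abs(rhos[best]):.3f} below floor "
            f"{correlation_floor}; developmental axis unreliable",
            stacklevel=2,
        )
    if rhos[best] < 0:  # orient mature stages positive
        projection.scores.iloc[:, best] *= -1
        projection.loadings.iloc[:, best] *= -1
        rhos[best] *= -1
    projection.developmental_pc = best
    projection.stage_correlation = float(rhos[best])
    return best


@dataclass
class MonotonicityResult:
    """Spearman monotonicity of line scores along the developmental axis."""

    rho: float
    p_value: float
    method: str
    n: int
    degenerate: bool = False


def monotonicity_score(
    projection: AtlasProjection, series: SampleSeries
) -> MonotonicityResult:
    """Spearman correlation of resistance rank with developmental score.

    Two-sided p by exact enumeration over all n! score orderings when
    n <= 8, asymptotic otherwise. With fewer than 4 lines the p-value is
    uninformative and the result is flagged degenerate.
    """
    scores = projection.developmental_scores()
    missing = [s for s in series.sample_ids if s not in scores.index]
    if missing:
        raise ValueError(f"line samples missing from projection: {missing}")
    x = series.resistance_rank.astype(float)
    y = scores[series.sample_ids].to_numpy(dtype=float)
    n = len(x)
    rho = float(stats.spearmanr(x, y)[0])
    degenerate = n < 4
    if degenerate:
        warnings.warn("fewer than 4 lines: p-value uninformative",
                      stacklevel=2)
    if n <= 8:
        count = 0
        total = math.factorial(n)
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(range(n)):
            r = stats.spearmanr(x, y[list(perm)])[0]
            if abs(r) >= target:
                count += 1
        return MonotonicityResult(rho, count / total, "exact-permutation",
                                  n, degenerate)
    p = float(stats.spearmanr(x, y)[1])
    return MonotonicityResult(rho, p, "asymptotic", n, degenerate)
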