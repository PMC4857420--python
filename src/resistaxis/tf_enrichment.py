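"""Transcription-factor target derivation and gene-list enrichment tests.

A gene is a target of a TF when any binding-site interval overlaps a window
around its TSS (default +/-5 kb, closed at both ends, strand-agnostic).
Gene lists are tested for target enrichment with a one-sided Fisher's exact
test (upper hypergeometric tail), and generic list-vs-list overlaps with the
same hypergeometric machinery. Raw p-values are reported by default, with a
Benjamini-Hochberg column available for sensitivity analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import GeneAnnotation

__all__ = [
    "TFTargetMap",
    "EnrichmentResult",
    "derive_targets",
    "fisher_target_enrichment",
    "fisher_from_table",
    "list_overlap_test",
    "enrichment_heatmap_table",
]


@dataclass
class TFTargetMap:
    """TF name -> target gene-id set, with the gene universe."""

    targets: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        for tf, genes in self.targets.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"{tf}: {len(extra)} targets outside the universe"
                )

    @property
    def tf_names(self) -> list[str]:
        return sorted(self.targets)


@dataclass
class EnrichmentResult:
    """One-sided Fisher enrichment of a gene list for TF targets.

    The 2x2 table cells are (in-list & target, in-list & not target,
    out-of-list & target, out-of-list & not target); they sum to the
    universe size.
    """

    name: str
    table: tuple[int, int, int, int]
    odds_ratio: float
    p_value: float
    degenerate: bool = False

    @property
    def neg_log10_p(self) -> float:
        return -np.log10(max(self.p_value, 1e-300))


def derive_targets(
    sites: pd.DataFrame,
    genes: GeneAnnotation,
    window: int = 5000,
    upstream_only: bool = False,
) -> TFTargetMap:
    """Assign target genes to TFs from binding intervals near TSSs.

    ``sites`` needs columns chrom, start, end (0-based half-open) and tf.
    A gene is a target of a TF iff any of its sites overlaps the closed
    position window [TSS-window, TSS+window] (with ``upstream_only``, the
    strand-aware closed window from TSS-window to TSS for plus-strand genes
    and TSS to TSS+window for minus-strand ones). Output is independent of
    site order; sites on chromosomes absent from the annotation are
    reported in a warning.
    """
    required = {"chrom", "start", "end", "tf"}
    if not required.issubset(sites.columns):
        raise ValueError(f"sites must have columns {sorted(required)}")
    if (sites["start"] >= sites["end"]).any():
        raise ValueError("binding intervals must satisfy start < end")

    trees: dict[str, IntervalTree] = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        tree = IntervalTree()
        for s, e, tf in zip(grp["start"], grp["end"], grp["tf"]):
            tree.addi(int(s), int(e), tf)
        trees[chrom] = tree

    unmatched = set(trees) - set(genes.frame["chrom"])
    if unmatched:
        warnings.warn(
            f"binding sites on chromosomes absent from annotation: "
            f"{sorted(unmatched)}",
            stacklevel=2,
        )

    targets: dict[str, set] = {tf: set() for tf in sites["tf"].unique()}
    for gid, row in genes.frame.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        tss = int(row["tss"])
        if upstream_only:
            if row["strand"] == "+":
                lo, hi = tss - window, tss
            else:
                lo, hi = tss, tss + window
        else:
            lo, hi = tss - window, tss + window
        # closed position window [lo, hi] == half-open [lo, hi+1)
        for iv in tree.overlap(lo, hi + 1):
            targets[iv.data].add(gid)

    return TFTargetMap(
        targets={tf: frozenset(g) for tf, g in sorted(targets.items())},
        universe=frozenset(genes.gene_ids),
    )


def _fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail hypergeometric p for a 2x2 table (enrichment direction)."""
    # P(X >= a) with X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b)
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio, Haldane-corrected only when a cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_target_enrichment(
    gene_list: Iterable[str],
    targets: TFTargetMap,
    tf: str,
) -> EnrichmentResult:
    """One-sided Fisher's exact test of a gene list for one TF's targets.

    The p-value is the exact upper hypergeometric tail (enrichment
    direction). The Haldane 0.5 correction applies to the reported odds
    ratio only when a cell is zero, never to the p-value. An empty list or
    empty target set is degenerate and yields p = 1.
    """
    gene_set = set(gene_list)
    extra = gene_set - targets.universe
    if extra:
        raise ValueError(
            f"{len(extra)} list genes outside the universe, e.g. "
            f"{sorted(extra)[:3]}"
        )
    tset = targets.targets[tf]
    a = len(gene_set & tset)
    b = len(gene_set) - a
    c = len(tset) - a
    d = len(targets.universe) - a - b - c
    if not gene_set or not tset:
        return EnrichmentResult(tf, (a, b, c, d), float("nan"), 1.0, True)
    return EnrichmentResult(
        tf, (a, b, c, d), _odds_ratio(a, b, c, d), _fisher_greater(a, b, c, d)
    )


def fisher_from_table(a: int, b: int, c: int, d: int, name: str = "table") -> EnrichmentResult:
    """One-sided Fisher enrichment test on explicit 2x2 counts.

    Cell layout: rows = (in list / flagged, not), columns = (target, not);
    ``a`` is the flagged-and-target cell.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or a + c == 0:
        return EnrichmentResult(name, (a, b, c, d), float("nan"), 1.0, True)
    return EnrichmentResult(
        name, (a, b, c, d), _odds_ratio(a, b, c, d), _fisher_greater(a, b, c, d)
    )


def list_overlap_test(
    list_a: Iterable[str] | int,
    list_b: Iterable[str] | int,
    universe_size: int,
    overlap: int | None = None,
) -> tuple[int, float]:
    """Upper-tail hypergeometric test of the overlap of two gene lists.

    Accepts either the two lists themselves (overlap computed) or their
    sizes plus an explicit ``overlap`` count. Returns (overlap, p) with
    p = P(overlap >= observed) under the hypergeometric null of drawing
    |B| genes from a universe containing |A| marked ones.
    """
    if isinstance(list_a, int) or isinstance(list_b, int):
        if not (isinstance(list_a, int) and isinstance(list_b, int)):
            raise TypeError("give two lists, or two sizes with overlap=")
        if overlap is None:
            raise ValueError("overlap count required with size inputs")
        na, nb, k = list_a, list_b, overlap
    else:
        sa, sb = set(list_a), set(list_b)
        na, nb, k = len(sa), len(sb), len(sa & sb)
        if overlap is not None and overlap != k:
            raise ValueError("explicit overlap disagrees with the lists")
    if na > universe_size or nb > universe_size:
        raise ValueError("list size exceeds universe size")
    if k > min(na, nb) or k < max(0, na + nb - universe_size):
        raise ValueError("overlap inconsistent with list and universe sizes")
    return k, float(stats.hypergeom.sf(k - 1, universe_size, na, nb))


def enrichment_heatmap_table(
    lists: Mapping[str, Iterable[str]],
    targets: TFTargetMap,
    with_bh: bool = False,
) -> pd.DataFrame:
    """-log10(p) matrix of TF-target enrichment, TFs x gene lists.

    p-values are floored at 1e-300 before the log. With ``with_bh`` an
    additional frame of Benjamini-Hochberg adjusted -log10 values (across
    TFs within each list) is returned alongside.
    """
    if not lists or not targets.targets:
        raise ValueError("need at least one gene list and one TF")
    raw = pd.DataFrame(
        {
            lname: {
                tf: fisher_target_enrichment(genes, targets, tf).p_value
                for tf in targets.tf_names
            }
            for lname, genes in ((n, list(g)) for n, g in lists.items())
        }
    ).loc[targets.tf_names]
    neglog = -np.log10(raw.clip(lower=1e-300))
    if not with_bh:
        return neglog
    adj = raw.apply(_benjamini_hochberg, axis=0)
    return neglog, -np.log10(adj.clip(lower=1e-300))


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    order = np.argsort(p.to_numpy())
    m = len(p)
    ranked = p.to_numpy()[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return pd.Series(out, index=p.index)
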