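"""Clinical cohort methylation analysis: per-CpG testing and gene linking.

A cohort of patients with binary outcome (responder / progressor) is
screened CpG by CpG with a two-sample Kolmogorov-Smirnov test on beta
values. CpGs are linked to genes when they fall inside the gene body or
within 10 kb of the TSS; a gene is flagged differentially methylated when
at least ``min_cpg`` of its linked CpGs are significant. The same
body-or-10-kb rule links TF binding regions to genes, and the resulting
2x2 contingency (differential x TF target) is tested with a one-sided
Fisher's exact test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .tf_enrichment import EnrichmentResult, fisher_from_table
from .types import GeneAnnotation

__all__ = [
    "ClinicalCohort",
    "ks_site_test",
    "ks_test_all_sites",
    "link_cpgs_to_genes",
    "link_regions_to_genes",
    "flag_differential_genes",
    "tf_contingency",
]

#: exact KS p-values when n1*n2 is at most this; asymptotic above
EXACT_KS_LIMIT = 10_000


@dataclass
class ClinicalCohort:
    """CpG beta-value matrix with patient outcomes and CpG coordinates.

    ``beta``: CpGs x patients, values in [0, 1] (NaN = missing).
    ``cpg_coords``: indexed by CpG id, columns chrom, pos (0-based).
    ``outcome``: patient id -> 'responder' | 'progressor'.
    """

    beta: pd.DataFrame
    cpg_coords: pd.DataFrame
    outcome: pd.Series

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate CpG ids in beta matrix")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if not set(self.outcome.unique()).issubset(
            {"responder", "progressor"}
        ):
            raise ValueError("outcomes must be 'responder' or 'progressor'")
        groups = set(self.outcome)
        if groups != {"responder", "progressor"}:
            raise ValueError("both outcome groups must be nonempty")
        missing = self.beta.index.difference(self.cpg_coords.index)
        if len(missing):
            raise ValueError(f"{len(missing)} CpGs lack coordinates")

    @property
    def responders(self) -> list[str]:
        return list(self.outcome.index[self.outcome == "responder"])

    @property
    def progressors(self) -> list[str]:
        return list(self.outcome.index[self.outcome == "progressor"])


def _ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """KS D (ECDF sup-difference) and p; exact when n1*n2 <= limit."""
    method = "exact" if len(x) * len(y) <= EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_site_test(
    cohort: ClinicalCohort, cpg: str, alpha: float = 0.05
) -> dict:
    """Two-sample KS test of one CpG's beta values between outcome groups.

    Uses pairwise-complete values per site; requires at least two
    non-missing patients in each group. Exact p by permutation-distribution
    enumeration when n1*n2 <= 10,000 (always true at 14 vs 5), asymptotic
    otherwise. Returns a dict with cpg, D, p and the significance flag at
    ``alpha``.
    """
    row = cohort.beta.loc[cpg]
    x = row[cohort.responders].dropna().to_numpy(dtype=float)
    y = row[cohort.progressors].dropna().to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"{cpg}: fewer than 2 complete patients in a group")
    d, p = _ks_two_sample(x, y)
    return {"cpg": cpg, "D": d, "p": p, "significant": p < alpha}


def ks_test_all_sites(
    cohort: ClinicalCohort, alpha: float = 0.05
) -> pd.DataFrame:
    """KS-test every CpG; returns a frame indexed by CpG id.

    Sites with fewer than two complete patients in either group are
    skipped; their count is reported in a warning and in the frame's
    ``attrs['n_skipped']``.
    """
    resp = cohort.beta[cohort.responders].to_numpy(dtype=float)
    prog = cohort.beta[cohort.progressors].to_numpy(dtype=float)
    rows, skipped = [], 0
    for i, cpg in enumerate(cohort.beta.index):
        x = resp[i][np.isfinite(resp[i])]
        y = prog[i][np.isfinite(prog[i])]
        if len(x) < 2 or len(y) < 2:
            skipped += 1
            continue
        d, p = _ks_two_sample(x, y)
        rows.append((cpg, d, p))
    if skipped:
        warnings.warn(f"skipped {skipped} CpGs with insufficient data",
                      stacklevel=2)
    out = pd.DataFrame(rows, columns=["cpg", "D", "p"]).set_index("cpg")
    out["significant"] = out["p"] < alpha
    out.attrs["n_skipped"] = skipped
    out.attrs["alpha"] = alpha
    return out


def _gene_link_trees(
    genes: GeneAnnotation, window: int
) -> dict[str, IntervalTree]:
    """Per-chromosome trees of gene link regions: body U [TSS-w, TSS+w].

    The TSS lies inside the body, so the union is one contiguous half-open
    interval [min(start, tss-w), max(end, tss+w+1)).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.frame.groupby("chrom", sort=False):
        tree = IntervalTree()
        for gid, row in grp.iterrows():
            lo = min(int(row["start"]), int(row["tss"]) - window)
            hi = max(int(row["end"]), int(row["tss"]) + window + 1)
            tree.addi(lo, hi, gid)
        trees[chrom] = tree
    return trees


def link_cpgs_to_genes(
    cpg_coords: pd.DataFrame,
    genes: GeneAnnotation,
    window: int = 10_000,
) -> pd.DataFrame:
    """Link CpGs to genes by position: gene body or within 10 kb of TSS.

    A CpG at position p links to a gene iff p is in the half-open body
    [start, end) or |p - TSS| <= window (closed boundary). A CpG may link
    to several genes. Returns a two-column frame (cpg, gene), one row per
    link, sorted for determinism.
    """
    trees = _gene_link_trees(genes, window)
    body = genes.frame
    links = []
    for cpg, row in cpg_coords.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        pos = int(row["pos"])
        for iv in tree.overlap(pos, pos + 1):
            g = body.loc[iv.data]
            in_body = g["start"] <= pos < g["end"]
            near_tss = abs(pos - g["tss"]) <= window
            if in_body or near_tss:
                links.append((cpg, iv.data))
    return (
        pd.DataFrame(links, columns=["cpg", "gene"])
        .sort_values(["gene", "cpg"])
        .reset_index(drop=True)
    )


def link_regions_to_genes(
    regions: pd.DataFrame,
    genes: GeneAnnotation,
    window: int = 10_000,
) -> dict[str, frozenset]:
    """Link interval regions (e.g. TF binding sites) to genes, per TF.

    ``regions`` needs columns chrom, start, end and tf. A region links to a
    gene when it overlaps the gene body or any position within ``window``
    of the TSS (same rule as CpG linking, applied to intervals). Returns
    tf -> linked gene set.
    """
    trees = _gene_link_trees(genes, window)
    body = genes.frame
    out: dict[str, set] = {tf: set() for tf in regions["tf"].unique()}
    for _, row in regions.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        s, e = int(row["start"]), int(row["end"])
        for iv in tree.overlap(s, e):
            g = body.loc[iv.data]
            hit_body = s < g["end"] and e > g["start"]
            # closed TSS window [tss-w, tss+w] vs half-open region [s, e)
            hit_tss = s <= g["tss"] + window and e - 1 >= g["tss"] - window
            if hit_body or hit_tss:
                out[row["tf"]].add(iv.data)
    return {tf: frozenset(g) for tf, g in out.items()}


def flag_differential_genes(
    links: pd.DataFrame,
    site_results: pd.DataFrame,
    min_cpg: int = 2,
) -> tuple[frozenset, pd.DataFrame]:
    """Flag genes with >= min_cpg linked significant CpGs.

    ``links`` as from :func:`link_cpgs_to_genes`; ``site_results`` as from
    :func:`ks_test_all_sites` (must cover the linked CpG universe). Returns
    (flagged gene set, per-gene support frame with the significant CpG
    count and the supporting CpG ids).
    """
    merged = links.merge(
        site_results["significant"], left_on="cpg", right_index=True,
        how="left",
    )
    merged["significant"] = merged["significant"].fillna(False)
    support = (
        merged[merged["significant"]]
        .groupby("gene")["cpg"]
        .agg(n_significant="size", cpgs=lambda s: ",".join(sorted(s)))
    )
    all_genes = merged.groupby("gene").size().rename("n_linked").to_frame()
    table = all_genes.join(support).fillna({"n_significant": 0, "cpgs": ""})
    table["n_significant"] = table["n_significant"].astype(int)
    table["flagged"] = table["n_significant"] >= min_cpg
    flagged = frozenset(table.index[table["flagged"]])
    return flagged, table


def tf_contingency(
    diff_genes: Iterable[str],
    tf_targets: Mapping[str, frozenset] | frozenset,
    universe: Iterable[str],
    tf: str | None = None,
) -> EnrichmentResult:
    """One-sided Fisher test of differential methylation vs TF targets.

    ``universe`` must be the genes that entered the linking computation.
    ``tf_targets`` is either a mapping tf -> gene set (then ``tf`` selects
    one) or a single gene set. Cells: (differential & target,
    differential & not, not differential & target, neither).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    if isinstance(tf_targets, Mapping):
        if tf is None:
            raise ValueError("tf name required with a target mapping")
        tset = set(tf_targets[tf])
        name = tf
    else:
        tset = set(tf_targets)
        name = tf or "targets"
    dset = set(diff_genes)
    if not dset <= uni or not tset <= uni:
        raise ValueError("differential and target genes must lie in universe")
    a = len(dset & tset)
    b = len(dset - tset)
    c = len(tset - dset)
    d = len(uni) - a - b - c
    return fisher_from_table(a, b, c, d, name=name)
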