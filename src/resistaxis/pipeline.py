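"""End-to-end orchestration: simulate, rank, chip, tfenrich, clinical, axis.

The pipeline runs the stages in dependency order from one configuration,
writes every product as plain text under an output directory, and records
a manifest (row counts and SHA-256 checksums) plus a summary of recovery
metrics against the planted ground truth. Identical config and seed give
identical checksums.
"""
from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .chip_enrichment import build_promoter_matrix, combinatorial_cluster, metagene_profile
from .clinical_methylation import (
    flag_differential_genes,
    link_cpgs_to_genes,
    link_regions_to_genes,
    ks_test_all_sites,
    tf_contingency,
)
from .developmental_axis import combined_pca, find_developmental_pc, monotonicity_score
from .resistance_covariance import covariance_with_resistance, select_extreme_features
from .synthetic_data import (
    GroundTruth,
    SynthConfig,
    generate_chip_counts,
    generate_clinical_cohort,
    generate_expression,
    generate_fragment_methylation,
    generate_reference_atlas,
    generate_tf_binding_sites,
    generate_variant_table,
    make_gene_annotation,
    make_series,
)
from .tf_enrichment import TFTargetMap, derive_targets, enrichment_heatmap_table

logger = logging.getLogger("resistaxis")

STAGES = ("simulate", "rank", "chip", "tfenrich", "clinical", "axis")


@dataclass
class RunConfig:
    """One-document configuration of a full pipeline run.

    Every published analysis threshold appears here with its default:
    50-bp bins, tau = 1e-6 with >= 3 bins in the 5-kb upstream promoter
    window, +/-5-kb TF target window, 10-kb clinical linking window,
    alpha = 0.05, >= 2 significant CpGs per flagged gene, top-list size
    1000.
    """

    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    synth: SynthConfig = field(default_factory=SynthConfig)
    covariate: str = "rank"
    top_size: int = 1000
    tau: float = 1e-6
    min_bins: int = 3
    promoter_window: int = 5000
    tf_window: int = 5000
    clinical_window: int = 10_000
    alpha: float = 0.05
    min_cpg: int = 2
    replicate_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if isinstance(self.synth, dict):
            self.synth = SynthConfig(**self.synth)
        self.synth.seed = self.seed
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tau <= 0 or self.min_bins < 1 or self.top_size < 1:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["synth"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d["synth"].items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _record(manifest: list, path: Path) -> None:
    manifest.append(
        {
            "path": path.name,
            "rows": rio.line_count(path),
            "sha256": rio.sha256_of(path),
        }
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages and write a manifest and summary.

    Returns the summary dict. Raises on stage failure after writing the
    partial manifest (``manifest.yaml``), naming the failed stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list = []
    summary: dict = {"seed": config.seed}
    enabled = [s for s in STAGES if config.stages.get(s)]
    if enabled and enabled[0] != "simulate":
        raise ValueError("downstream stages need the simulate stage enabled")

    state: dict = {}
    current = None
    try:
        for stage in enabled:
            current = stage
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](config, out, state, manifest, summary)
            logger.info("stage %s done in %.1fs", stage,
                        time.perf_counter() - t0)
    except Exception:
        _write_yaml(out / "manifest.yaml", manifest)
        logger.error("pipeline aborted in stage %r", current)
        raise
    _write_yaml(out / "manifest.yaml", manifest)
    _write_yaml(out / "summary.yaml", summary)
    return summary


def _write_yaml(path: Path, payload) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _stage_simulate(config, out, state, manifest, summary):
    sc = config.synth
    series = make_series(sc)
    annotation = make_gene_annotation(sc)
    expr, gt_e = generate_expression(sc)
    frags, coverage, gt_f = generate_fragment_methylation(sc)
    alt, ref, gt_v = generate_variant_table(sc)
    tracks, gt_c = generate_chip_counts(sc, annotation)
    planted_pos = [f for f, d, _ in gt_e.planted_covarying_features if d > 0]
    sites, gt_t = generate_tf_binding_sites(sc, annotation, planted_pos)
    cohort, gt_cl = generate_clinical_cohort(
        sc, annotation, gt_t.planted_tf_targets
    )
    reference, stages, lines, gt_a = generate_reference_atlas(sc)

    gt = gt_e
    for g in (gt_f, gt_v, gt_c, gt_t, gt_cl, gt_a):
        gt = gt.merge(g)

    state.update(
        series=series, annotation=annotation, expression=expr,
        fragments=frags, coverage=coverage, alt=alt, ref=ref,
        tracks=tracks, sites=sites, cohort=cohort,
        reference=reference, stages=stages, lines=lines, ground_truth=gt,
    )

    rio.write_series(series, out / "samples.tsv")
    annotation.to_bed(out / "genes.bed")
    rio.write_matrix(expr, out / "expression.tsv")
    rio.write_matrix(frags, out / "fragment_methylation.tsv")
    rio.write_intervals_bed(frags.intervals, out / "fragments.bed")
    alt.to_csv(out / "alt_counts.tsv", sep="\t")
    ref.to_csv(out / "ref_counts.tsv", sep="\t")
    rio.write_sites_bed(sites, out / "tf_sites.bed")
    cohort.beta.to_csv(out / "clinical_beta.tsv", sep="\t",
                       float_format="%.6g")
    cohort.outcome.to_frame().to_csv(out / "clinical_labels.tsv", sep="\t")
    coords = cohort.cpg_coords
    pd.DataFrame(
        {"chrom": coords["chrom"], "start": coords["pos"],
         "end": coords["pos"] + 1, "name": coords.index}
    ).to_csv(out / "clinical_cpgs.bed", sep="\t", header=False, index=False)
    rio.write_matrix(reference, out / "atlas_reference.tsv")
    rio.write_matrix(lines, out / "atlas_lines.tsv")
    stages.to_frame().to_csv(out / "atlas_stages.tsv", sep="\t")
    for cond, reps in tracks.items():
        for t in reps:
            rio.write_track(t, out / f"chip_{cond}_{t.replicate}.tsv")
    gt.to_yaml(out / "ground_truth.yaml")
    sc.to_yaml(out / "synth_config.yaml")
    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.bed")) + [
        out / "ground_truth.yaml", out / "synth_config.yaml"
    ]:
        _record(manifest, p)


def _stage_rank(config, out, state, manifest, summary):
    series = state["series"]
    gt: GroundTruth = state["ground_truth"]
    import warnings as _warnings

    cov = covariance_with_resistance(state["expression"], series,
                                     config.covariate)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # top_size may exceed n_features
        ranking = select_extreme_features(cov, config.top_size)
    ranking.table.to_csv(out / "expression_ranking.tsv", sep="\t")
    _record(manifest, out / "expression_ranking.tsv")
    state["ranking"] = ranking

    # recall scored on a planted-matched top list, independent of top_size
    planted_pos = {f for f, d, _ in gt.planted_covarying_features if d > 0}
    if planted_pos:
        matched = select_extreme_features(cov, len(planted_pos))
        recall = len(planted_pos & set(matched.top)) / len(planted_pos)
    else:
        recall = float("nan")
    summary["top_gene_recall"] = round(float(recall), 4)

    mcov = covariance_with_resistance(state["fragments"], series,
                                      config.covariate)
    mrank = select_extreme_features(mcov, ranking.size)
    mrank.table.to_csv(out / "methylation_ranking.tsv", sep="\t")
    _record(manifest, out / "methylation_ranking.tsv")
    state["meth_ranking"] = mrank

    from .resistance_covariance import vaf_trend_screen

    screen = vaf_trend_screen(state["alt"], state["ref"], series)
    screen.to_csv(out / "variant_screen.tsv", sep="\t")
    _record(manifest, out / "variant_screen.tsv")
    singles = set(gt.planted_variant_singletons)
    found = set(screen.index[screen["singleton_suspect"]])
    summary["singleton_artifacts_flagged"] = len(singles & found)


def _stage_chip(config, out, state, manifest, summary):
    gt: GroundTruth = state["ground_truth"]
    matrix = build_promoter_matrix(
        state["tracks"], state["annotation"],
        condition_order=state["series"].sample_ids,
        window=config.promoter_window, tau=config.tau,
        min_bins=config.min_bins, replicate_mode=config.replicate_mode,
    )
    clusters = combinatorial_cluster(matrix)
    matrix.calls.to_csv(out / "promoter_calls.tsv", sep="\t")
    clusters.to_csv(out / "promoter_clusters.tsv", sep="\t")
    _record(manifest, out / "promoter_calls.tsv")
    _record(manifest, out / "promoter_clusters.tsv")
    state["promoter_matrix"] = matrix
    state["promoter_clusters"] = clusters

    truth = pd.Series(gt.planted_promoter_groups)
    planted = truth[truth.isin(["K1", "K2", "K3"])]
    agree = (clusters.loc[planted.index, "label"] == planted).mean()
    summary["promoter_label_recovery"] = round(float(agree), 4)

    k2 = truth.index[truth == "K2"]
    if len(k2):
        profile = metagene_profile(state["tracks"], state["annotation"],
                                   list(k2), flank=config.promoter_window)
        profile.to_csv(out / "metagene_K2.tsv", sep="\t")
        _record(manifest, out / "metagene_K2.tsv")


def _stage_tfenrich(config, out, state, manifest, summary):
    gt: GroundTruth = state["ground_truth"]
    targets = derive_targets(state["sites"], state["annotation"],
                             window=config.tf_window)
    lists = {
        "high_covariance": state["ranking"].top,
        "low_covariance": state["ranking"].bottom,
    }
    table = enrichment_heatmap_table(lists, targets)
    table.to_csv(out / "tf_enrichment.tsv", sep="\t")
    _record(manifest, out / "tf_enrichment.tsv")
    state["tf_targets"] = targets
    planted_tf = config.synth.planted_tf
    summary["planted_tf_is_max"] = bool(
        table["high_covariance"].idxmax() == planted_tf
    )
    exact = all(
        targets.targets[tf] == frozenset(gt.planted_tf_targets[tf])
        for tf in gt.planted_tf_targets
    )
    summary["tf_target_derivation_exact"] = bool(exact)


def _stage_clinical(config, out, state, manifest, summary):
    cohort = state["cohort"]
    gt: GroundTruth = state["ground_truth"]
    sites_df = ks_test_all_sites(cohort, alpha=config.alpha)
    sites_df.to_csv(out / "clinical_site_tests.tsv", sep="\t")
    _record(manifest, out / "clinical_site_tests.tsv")

    coords = cohort.cpg_coords.rename(columns={"pos": "pos"})
    links = link_cpgs_to_genes(coords, state["annotation"],
                               window=config.clinical_window)
    flagged, support = flag_differential_genes(links, sites_df,
                                               min_cpg=config.min_cpg)
    support.to_csv(out / "clinical_gene_support.tsv", sep="\t")
    _record(manifest, out / "clinical_gene_support.tsv")

    tf_linked = link_regions_to_genes(state["sites"], state["annotation"],
                                      window=config.clinical_window)
    planted_tf = config.synth.planted_tf
    result = tf_contingency(flagged, tf_linked, state["annotation"].gene_ids,
                            tf=planted_tf)
    report = {
        "tf": planted_tf,
        "table": [int(x) for x in result.table],
        "odds_ratio": float(result.odds_ratio),
        "p_value": float(result.p_value),
        "n_flagged": len(flagged),
        "n_significant_cpgs": int(sites_df["significant"].sum()),
    }
    _write_yaml(out / "clinical_contingency.yaml", report)
    _record(manifest, out / "clinical_contingency.yaml")
    summary["clinical_odds_ratio"] = round(report["odds_ratio"], 3)
    summary["clinical_p_value"] = float(report["p_value"])
    planted = gt.planted_clinical_dmg
    if planted:
        summary["clinical_dmg_recall"] = round(
            len(planted & set(flagged)) / len(planted), 4
        )


def _stage_axis(config, out, state, manifest, summary):
    projection = combined_pca(state["reference"], state["lines"])
    pc = find_developmental_pc(projection, state["stages"])
    mono = monotonicity_score(projection, state["series"])
    projection.scores.to_csv(out / "axis_scores.tsv", sep="\t",
                             float_format="%.6g")
    _record(manifest, out / "axis_scores.tsv")
    _write_yaml(
        out / "axis_summary.yaml",
        {
            "developmental_pc": int(pc + 1),
            "stage_correlation": float(projection.stage_correlation),
            "monotonicity_rho": float(mono.rho),
            "monotonicity_p": float(mono.p_value),
            "n_genes_used": projection.n_genes_used,
        },
    )
    _record(manifest, out / "axis_summary.yaml")
    summary["developmental_pc"] = int(pc + 1)
    summary["monotonicity_rho"] = round(float(mono.rho), 4)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rank": _stage_rank,
    "chip": _stage_chip,
    "tfenrich": _stage_tfenrich,
    "clinical": _stage_clinical,
    "axis": _stage_axis,
}
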