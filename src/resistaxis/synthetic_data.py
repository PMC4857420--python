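"""Synthetic multi-omics data with planted, recoverable structure.

Every input the analysis pipeline consumes can be generated here: a
five-line dose-escalation series (parental plus four resistant lines) with
log2 expression, RRBS-style fragment methylation, variant allele counts,
binned H3K27me3 IP/input ChIP counts, TF binding sites, a clinical
methylation cohort (14 responders vs 5 progressors) and a staged reference
expression atlas. Planted effects — covarying features, promoter dynamics
groups, TF target sets, differentially methylated genes, developmental
placements — are recorded in a :class:`GroundTruth` so recovery tests can
score every downstream method against construction.

Noise models are deliberately minimal and matched to each data type's
support: Gaussian noise on log2 expression, Beta noise on methylation
fractions, Poisson counts for ChIP bins, binomial allele counts. All
generators are deterministic given (config, seed): each draws from its own
`numpy` SeedSequence stream keyed by the config seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .chip_enrichment import BIN_WIDTH, BinTrack
from .clinical_methylation import ClinicalCohort
from .types import FeatureMatrix, GeneAnnotation, SampleSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "make_series",
    "make_gene_annotation",
    "generate_expression",
    "generate_fragment_methylation",
    "generate_variant_table",
    "generate_chip_counts",
    "generate_tf_binding_sites",
    "generate_clinical_cohort",
    "generate_reference_atlas",
]

# fixed stream tags so each generator has an independent, reproducible RNG
_STREAMS = {
    "expression": 1,
    "fragments": 2,
    "variants": 3,
    "chip": 4,
    "tf": 5,
    "clinical": 6,
    "atlas": 7,
}

_CANONICAL_NAMES = ("Parental", "R100", "R500", "R1000", "R4000")
#: EC50 endpoints measured for the parental and most resistant line (nM);
#: interior values interpolated and freely configurable.
_DEFAULT_EC50 = (857.0, 1100.0, 1700.0, 2500.0, 3446.0)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; defaults mirror the study design.

    The series is a parental line plus four lines of increasing resistance
    with strictly increasing EC50 (nM). Fractions lie in [0, 1]; depths and
    folds are positive. ``seed`` drives every generator stream.
    """

    # series
    n_samples: int = 5
    ec50_values: tuple = _DEFAULT_EC50
    # expression layer
    n_genes: int = 2000
    fraction_covarying: float = 0.05
    effect_size: float = 1.0          # log2 units per resistance rank
    noise_sd: float = 0.3             # within-gene Gaussian noise, log2 units
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    # genome layout
    gene_spacing: int = 20_000
    gene_length: int = 8_000
    first_tss: int = 10_000
    chrom: str = "chr1"
    # RRBS fragment layer
    n_fragments: int = 3000
    meth_effect: float = 0.08         # methylation-fraction drift per rank
    meth_precision: float = 50.0      # Beta precision (a+b)
    fragment_coverage: float = 30.0
    # variant layer
    n_variants: int = 500
    n_trend_variants: int = 10
    n_singleton_artifacts: int = 13
    variant_depth: float = 30.0
    # ChIP layer
    bin_width: int = BIN_WIDTH
    promoter_window: int = 5000       # bp strictly upstream of the TSS
    n_k1: int = 150
    n_k2: int = 150
    n_other: int = 100                # random non-canonical patterns; rest K3
    ip_depth: float = 10.0            # expected IP reads/bin/replicate, background
    input_depth: float = 10.0
    enrichment_fold: float = 4.0
    n_replicates: int = 2
    # TF layer
    planted_tf: str = "Tcf3"
    decoy_tfs: tuple = ("Suz12", "Pcl2", "Pu1", "Myc", "Foxo1")
    targets_per_tf: int = 300
    planted_target_weight: float = 10.0
    # clinical layer
    n_patients_responder: int = 14
    n_patients_progressor: int = 5
    cpgs_per_gene: int = 4
    n_shifted_cpgs: int = 3
    beta_shift: float = 0.25
    beta_precision: float = 50.0
    dmg_rate_nontarget: float = 0.05
    clinical_target_odds: float = 4.0
    # reference atlas
    n_stages: int = 8
    atlas_replicates: int = 3
    fraction_developmental: float = 0.15
    fraction_source: float = 0.35
    atlas_noise_sd: float = 0.05
    dev_amplitude: float = 1.0
    source_offset: float = 1.0
    # line placements average 0.5 = the reference stage mean, keeping the
    # reference/line source component orthogonal to the stage gradient
    line_stage_start: float = 0.8
    line_stage_step: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.ec50_values = tuple(self.ec50_values)
        self.decoy_tfs = tuple(self.decoy_tfs)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples in the series")
        if len(self.ec50_values) != self.n_samples:
            raise ValueError("ec50_values must have one entry per sample")
        if np.any(np.diff(self.ec50_values) <= 0):
            raise ValueError("ec50_values must be strictly increasing")
        for name in (
            "fraction_covarying",
            "fraction_developmental",
            "fraction_source",
            "dmg_rate_nontarget",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "ip_depth", "input_depth", "enrichment_fold", "variant_depth",
            "fragment_coverage", "meth_precision", "beta_precision",
            "clinical_target_odds",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_k1 + self.n_k2 + self.n_other > self.n_genes:
            raise ValueError("promoter group sizes exceed n_genes")
        if self.n_stages < 3:
            raise ValueError("need at least 3 atlas stages")
        if self.n_shifted_cpgs > self.cpgs_per_gene:
            raise ValueError("n_shifted_cpgs cannot exceed cpgs_per_gene")

    @property
    def sample_names(self) -> list[str]:
        if self.n_samples == len(_CANONICAL_NAMES):
            return list(_CANONICAL_NAMES)
        return ["Parental"] + [f"R{i}" for i in range(1, self.n_samples)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ec50_values", "decoy_tfs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted structure of one synthetic study, for recovery scoring.

    ``planted_covarying_features``: (feature id, direction +/-1, effect per
    unit rank) for the expression layer; ``planted_fragment_features`` the
    same for methylation fragments. Promoter groups map promoter (gene) id
    to K1/K2/K3/other. All ids exist in the generated datasets.
    """

    seed: int
    planted_covarying_features: list = field(default_factory=list)
    planted_fragment_features: list = field(default_factory=list)
    planted_promoter_groups: dict = field(default_factory=dict)
    planted_promoter_patterns: dict = field(default_factory=dict)
    planted_tf_targets: dict = field(default_factory=dict)
    planted_clinical_dmg: set = field(default_factory=set)
    planted_variant_trend: list = field(default_factory=list)
    planted_variant_singletons: list = field(default_factory=list)
    planted_stage_positions: dict = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        if other.seed != self.seed:
            raise ValueError("cannot merge ground truths from different seeds")
        out = GroundTruth(seed=self.seed)
        for name in (
            "planted_covarying_features",
            "planted_fragment_features",
            "planted_variant_trend",
            "planted_variant_singletons",
        ):
            setattr(out, name, getattr(self, name) + getattr(other, name))
        for name in (
            "planted_promoter_groups",
            "planted_promoter_patterns",
            "planted_tf_targets",
            "planted_stage_positions",
        ):
            setattr(out, name, {**getattr(self, name), **getattr(other, name)})
        out.planted_clinical_dmg = (
            self.planted_clinical_dmg | other.planted_clinical_dmg
        )
        return out

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_covarying_features": [
                [f, int(d), float(e)]
                for f, d, e in self.planted_covarying_features
            ],
            "planted_fragment_features": [
                [f, int(d), float(e)]
                for f, d, e in self.planted_fragment_features
            ],
            "planted_promoter_groups": dict(
                sorted(self.planted_promoter_groups.items())
            ),
            "planted_promoter_patterns": dict(
                sorted(self.planted_promoter_patterns.items())
            ),
            "planted_tf_targets": {
                str(tf): sorted(str(g) for g in genes)
                for tf, genes in sorted(self.planted_tf_targets.items())
            },
            "planted_clinical_dmg": sorted(
                str(g) for g in self.planted_clinical_dmg
            ),
            "planted_variant_trend": sorted(self.planted_variant_trend),
            "planted_variant_singletons": sorted(
                self.planted_variant_singletons
            ),
            "planted_stage_positions": {
                k: float(v)
                for k, v in sorted(self.planted_stage_positions.items())
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def make_series(config: SynthConfig) -> SampleSeries:
    """The dose-escalation sample series implied by the config."""
    return SampleSeries(
        sample_ids=config.sample_names,
        resistance_rank=np.arange(config.n_samples),
        ec50=np.asarray(config.ec50_values, dtype=float),
    )


def make_gene_annotation(config: SynthConfig) -> GeneAnnotation:
    """Evenly spaced gene models on one chromosome, alternating strands.

    Gene *i* has its TSS at ``first_tss + i*gene_spacing``; plus-strand
    bodies run downstream, minus-strand bodies upstream, so the TSS always
    sits at the body edge and 5-kb promoter windows never collide.
    """
    ids = [f"g{i:05d}" for i in range(config.n_genes)]
    tss = config.first_tss + np.arange(config.n_genes) * config.gene_spacing
    strand = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    start = np.where(strand == "+", tss, tss - config.gene_length + 1)
    end = np.where(strand == "+", tss + config.gene_length, tss + 1)
    frame = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "tss": tss,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return GeneAnnotation(frame)


def _planted_split(ids: list[str], fraction: float,
                   rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Pick planted feature ids and alternate +/- directions."""
    n_planted = int(round(fraction * len(ids)))
    if n_planted < 1:
        warnings.warn("fraction_covarying too small: zero planted features",
                      stacklevel=3)
        return [], np.array([], dtype=int)
    chosen = sorted(rng.choice(len(ids), size=n_planted, replace=False))
    planted = [ids[i] for i in chosen]
    directions = np.where(np.arange(n_planted) % 2 == 0, 1, -1)
    return planted, directions


def generate_expression(
    config: SynthConfig,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Log2 expression matrix with planted resistance-covarying genes.

    Planted genes follow baseline + direction*effect_size*rank plus
    Gaussian noise; the rest are noise around gene-specific baselines.
    """
    rng = config.rng("expression")
    series = make_series(config)
    ids = [f"g{i:05d}" for i in range(config.n_genes)]
    baselines = rng.normal(config.baseline_mean, config.baseline_sd,
                           size=config.n_genes)
    values = np.tile(baselines[:, None], (1, config.n_samples))

    planted, directions = _planted_split(ids, config.fraction_covarying, rng)
    idx = {g: i for i, g in enumerate(ids)}
    ranks = series.resistance_rank.astype(float)
    for g, d in zip(planted, directions):
        values[idx[g]] += d * config.effect_size * ranks
    values += rng.normal(0.0, config.noise_sd,
                         size=values.shape) if config.noise_sd > 0 else 0.0

    gt = GroundTruth(
        seed=config.seed,
        planted_covarying_features=[
            (g, int(d), float(config.effect_size))
            for g, d in zip(planted, directions)
        ],
    )
    matrix = FeatureMatrix(
        values=pd.DataFrame(values, index=pd.Index(ids, name="gene_id"),
                            columns=series.sample_ids),
        value_kind="log2_expression",
    )
    return matrix, gt


def _beta_draw(rng: np.random.Generator, mean: np.ndarray,
               precision: float) -> np.ndarray:
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mean * precision, (1 - mean) * precision)


def generate_fragment_methylation(
    config: SynthConfig,
) -> tuple[FeatureMatrix, pd.DataFrame, GroundTruth]:
    """RRBS-style fragment methylation with planted covarying fragments.

    Fragment baselines are drawn from a bimodal (mostly low / mostly high)
    mixture as in real RRBS; planted fragments drift by
    direction*meth_effect per rank, with Beta-distributed noise at
    ``meth_precision``. Returns (matrix, per-sample coverage/CpG-count
    frame, ground truth).
    """
    rng = config.rng("fragments")
    series = make_series(config)
    ids = [f"frag{i:05d}" for i in range(config.n_fragments)]
    low = rng.uniform(0.03, 0.2, size=config.n_fragments)
    high = rng.uniform(0.6, 0.95, size=config.n_fragments)
    base = np.where(rng.random(config.n_fragments) < 0.6, low, high)

    planted, directions = _planted_split(ids, config.fraction_covarying, rng)
    idx = {g: i for i, g in enumerate(ids)}
    ranks = series.resistance_rank.astype(float)
    means = np.tile(base[:, None], (1, config.n_samples))
    for g, d in zip(planted, directions):
        # keep planted baselines mid-range so the drift has room
        start = 0.25 if d > 0 else 0.75
        means[idx[g]] = start + d * config.meth_effect * ranks
    clipped = (means < 0) | (means > 1)
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} planted methylation means clipped to (0,1)",
            stacklevel=2,
        )
    means = np.clip(means, 0.01, 0.99)
    values = _beta_draw(rng, means, config.meth_precision)

    frag_start = rng.integers(
        0, config.n_genes * config.gene_spacing, size=config.n_fragments
    )
    frag_len = rng.integers(100, 301, size=config.n_fragments)
    intervals = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": frag_start,
            "end": frag_start + frag_len,
            "strand": ".",
        },
        index=pd.Index(ids, name="fragment_id"),
    )
    coverage = pd.DataFrame(
        rng.poisson(config.fragment_coverage,
                    size=(config.n_fragments, config.n_samples)) + 5,
        index=intervals.index,
        columns=series.sample_ids,
    )
    coverage["n_cpg"] = rng.integers(4, 25, size=config.n_fragments)

    gt = GroundTruth(
        seed=config.seed,
        planted_fragment_features=[
            (g, int(d), float(config.meth_effect))
            for g, d in zip(planted, directions)
        ],
    )
    matrix = FeatureMatrix(
        values=pd.DataFrame(values, index=intervals.index,
                            columns=series.sample_ids),
        value_kind="methylation_fraction",
        intervals=intervals,
    )
    return matrix, coverage, gt


def generate_variant_table(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-sample ref/alt allele counts with planted trends and artifacts.

    Most variants have a constant underlying allele frequency. Planted
    *trend* variants increase linearly in frequency with resistance rank;
    planted *singleton artifacts* carry alt reads in exactly the most
    resistant sample, emulating alignment artifacts at read ends or in
    repeats. Returns (alt counts, ref counts, ground truth).
    """
    rng = config.rng("variants")
    series = make_series(config)
    n = config.n_variants
    n_trend = config.n_trend_variants
    n_single = config.n_singleton_artifacts
    if n_trend + n_single > n:
        raise ValueError("planted variant counts exceed n_variants")
    ids = [f"var{i:05d}" for i in range(n)]
    roles = np.array(["null"] * n, dtype=object)
    special = rng.choice(n, size=n_trend + n_single, replace=False)
    roles[special[:n_trend]] = "trend"
    roles[special[n_trend:]] = "singleton"

    ranks = series.resistance_rank.astype(float)
    max_rank = ranks.max()
    af = np.empty((n, config.n_samples))
    base_af = rng.uniform(0.05, 0.6, size=n)
    for i in range(n):
        if roles[i] == "trend":
            af[i] = 0.05 + (0.45 / max_rank) * ranks
        elif roles[i] == "singleton":
            af[i] = np.where(ranks == max_rank, 0.3, 0.0)
        else:
            af[i] = base_af[i]
    depth = rng.poisson(config.variant_depth, size=(n, config.n_samples))
    alt = rng.binomial(depth, af)
    # artifacts must show alt reads in exactly one sample by construction
    for i in np.flatnonzero(roles == "singleton"):
        j = int(np.argmax(ranks))
        if alt[i, j] == 0:
            alt[i, j] = 1
    ref = depth - alt

    index = pd.Index(ids, name="variant_id")
    gt = GroundTruth(
        seed=config.seed,
        planted_variant_trend=[ids[i] for i in np.flatnonzero(roles == "trend")],
        planted_variant_singletons=[
            ids[i] for i in np.flatnonzero(roles == "singleton")
        ],
    )
    cols = series.sample_ids
    return (
        pd.DataFrame(alt, index=index, columns=cols),
        pd.DataFrame(ref, index=index, columns=cols),
        gt,
    )


# --- ChIP layer -----------------------------------------------------------

_K2_PATTERN = "01100"  # gain at R100/R500, loss by R1000 and R4000


def _k2_family(n_conditions: int) -> set[str]:
    """Patterns labelled K2 by the default rule (n=5 conditions)."""
    out = set()
    for a in "01":
        for b in "01":
            for c in "01":
                if a == b == "0":
                    continue
                out.add("0" + a + b + c + "0")
    return out


def _assign_promoter_patterns(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Assign each gene a dynamics group and a binary pattern."""
    if config.n_samples != 5:
        raise ValueError("promoter dynamics groups assume a 5-condition series")
    n = config.n_genes
    order = rng.permutation(n)
    groups = {}
    patterns = {}
    ids = [f"g{i:05d}" for i in range(n)]
    k1 = set(order[: config.n_k1])
    k2 = set(order[config.n_k1: config.n_k1 + config.n_k2])
    other = set(order[config.n_k1 + config.n_k2:
                      config.n_k1 + config.n_k2 + config.n_other])
    canonical = {"11111", "00000"} | _k2_family(5)
    other_pool = sorted(
        {format(i, "05b") for i in range(32)} - canonical
    )
    for i in range(n):
        gid = ids[i]
        if i in k1:
            groups[gid], patterns[gid] = "K1", "11111"
        elif i in k2:
            groups[gid], patterns[gid] = "K2", _K2_PATTERN
        elif i in other:
            groups[gid] = "other"
            patterns[gid] = other_pool[rng.integers(len(other_pool))]
        else:
            groups[gid], patterns[gid] = "K3", "00000"
    return groups, patterns


def generate_chip_counts(
    config: SynthConfig,
    annotation: GeneAnnotation | None = None,
) -> tuple[dict, GroundTruth]:
    """Poisson IP/input bin counts with planted promoter dynamics.

    Bins tile +/-6 kb around every TSS on a global 50-bp grid. Input counts
    are Poisson(``input_depth``) everywhere; IP counts are
    Poisson(``ip_depth``), raised to ``enrichment_fold`` times background
    within the 5-kb upstream promoter window in conditions where the
    promoter's planted pattern is 1. With ``enrichment_fold`` = 1 no
    promoter is distinguishable from background.

    Returns ({condition: [BinTrack per replicate]}, ground truth).
    """
    rng = config.rng("chip")
    if annotation is None:
        annotation = make_gene_annotation(config)
    series = make_series(config)
    groups, patterns = _assign_promoter_patterns(config, rng)

    flank = config.promoter_window + 1000
    tss = annotation.frame["tss"].to_numpy()
    strand = annotation.frame["strand"].to_numpy()
    starts = []
    enriched_mask_per_gene = []
    for t, s in zip(tss, strand):
        lo = ((t - flank) // BIN_WIDTH) * BIN_WIDTH
        hi = ((t + flank) // BIN_WIDTH) * BIN_WIDTH
        gene_bins = np.arange(lo, hi, BIN_WIDTH)
        starts.append(gene_bins)
        if s == "+":
            wlo, whi = t - config.promoter_window, t
        else:
            wlo, whi = t + 1, t + 1 + config.promoter_window
        enriched_mask_per_gene.append(
            (gene_bins < whi) & (gene_bins + BIN_WIDTH > wlo)
        )
    bins_per_gene = np.array([len(s) for s in starts])
    starts = np.concatenate(starts)
    promoter_mask = np.concatenate(enriched_mask_per_gene)
    gene_ids = annotation.frame.index.to_numpy()
    # genes x conditions boolean: planted pattern has a 1 in that condition
    pat_bool = np.array(
        [[ch == "1" for ch in patterns[g]] for g in gene_ids]
    )

    tracks: dict[str, list[BinTrack]] = {}
    for ci, cond in enumerate(series.sample_ids):
        cond_enriched = promoter_mask & np.repeat(
            pat_bool[:, ci], bins_per_gene
        )
        ip_mean = np.where(
            cond_enriched,
            config.ip_depth * config.enrichment_fold,
            config.ip_depth,
        )
        reps = []
        for r in range(config.n_replicates):
            bins = pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "start": starts,
                    "end": starts + BIN_WIDTH,
                    "ip": rng.poisson(ip_mean),
                    "input": rng.poisson(config.input_depth, size=len(starts)),
                }
            )
            reps.append(
                BinTrack(condition=cond, replicate=f"rep{r + 1}", bins=bins)
            )
        tracks[cond] = reps

    gt = GroundTruth(
        seed=config.seed,
        planted_promoter_groups=groups,
        planted_promoter_patterns=patterns,
    )
    return tracks, gt


def generate_tf_binding_sites(
    config: SynthConfig,
    annotation: GeneAnnotation | None = None,
    planted_positive_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """BED-like TF binding sites with one planted, signal-coupled TF.

    Each TF gets ``targets_per_tf`` target genes and one 200-bp site within
    +/-4.5 kb of each target's TSS (inside the 5-kb derivation window).
    The planted TF's targets are sampled with ``planted_target_weight``-fold
    weight on the planted positively covarying genes, so top-covariance
    lists are enriched for its targets; decoy TFs sample uniformly.
    """
    rng = config.rng("tf")
    if annotation is None:
        annotation = make_gene_annotation(config)
    ids = list(annotation.gene_ids)
    planted_positive = set(planted_positive_genes or [])

    targets: dict[str, frozenset] = {}
    all_tfs = [config.planted_tf, *config.decoy_tfs]
    for tf in all_tfs:
        if tf == config.planted_tf and planted_positive:
            w = np.array(
                [config.planted_target_weight if g in planted_positive else 1.0
                 for g in ids]
            )
            w = w / w.sum()
            chosen = rng.choice(ids, size=config.targets_per_tf,
                                replace=False, p=w)
        else:
            chosen = rng.choice(ids, size=config.targets_per_tf,
                                replace=False)
        targets[tf] = frozenset(str(g) for g in chosen)

    rows = []
    tss = annotation.frame["tss"]
    for tf in all_tfs:
        for g in sorted(targets[tf]):
            offset = int(rng.integers(-4500, 4300))
            s = int(tss[g]) + offset
            rows.append((config.chrom, s, s + 200, tf))
    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])
    gt = GroundTruth(seed=config.seed, planted_tf_targets=dict(targets))
    return sites, gt


def generate_clinical_cohort(
    config: SynthConfig,
    annotation: GeneAnnotation | None = None,
    tf_targets: dict | None = None,
) -> tuple[ClinicalCohort, GroundTruth]:
    """Beta-value cohort (responders vs progressors) with planted DMGs.

    Each annotated gene carries ``cpgs_per_gene`` CpGs placed inside the
    gene body or within 10 kb of the TSS. Differentially methylated genes
    are planted per-gene with base rate ``dmg_rate_nontarget``, raised to
    ``clinical_target_odds`` on the odds scale for targets of the planted
    TF; a planted gene has ``n_shifted_cpgs`` CpGs whose progressor-group
    mean is shifted by ``beta_shift`` (clipped into (0,1) with a warning).
    With ``beta_shift`` = 0 or zero rates nothing is planted and the
    cohort is null.
    """
    rng = config.rng("clinical")
    if annotation is None:
        annotation = make_gene_annotation(config)
    if tf_targets is None:
        tf_targets = {}
    target_set = set(tf_targets.get(config.planted_tf, frozenset()))

    n_resp = config.n_patients_responder
    n_prog = config.n_patients_progressor
    patients = [f"resp{i + 1:02d}" for i in range(n_resp)] + [
        f"prog{i + 1:02d}" for i in range(n_prog)
    ]
    outcome = pd.Series(
        ["responder"] * n_resp + ["progressor"] * n_prog,
        index=pd.Index(patients, name="patient"),
        name="outcome",
    )

    # plant DMGs with higher odds among planted-TF targets
    base = config.dmg_rate_nontarget
    if base > 0 and config.beta_shift > 0:
        odds_nt = base / (1 - base)
        odds_t = odds_nt * config.clinical_target_odds
        p_t = odds_t / (1 + odds_t)
        p_gene = np.array(
            [p_t if g in target_set else base for g in annotation.gene_ids]
        )
        dmg = {
            str(g)
            for g in np.asarray(annotation.gene_ids)[
                rng.random(len(p_gene)) < p_gene
            ]
        }
    else:
        dmg = set()

    cpg_rows = []
    means = []
    shifted = []
    body = annotation.frame
    k = 0
    for gid, row in body.iterrows():
        gene_dmg = gid in dmg
        for j in range(config.cpgs_per_gene):
            cid = f"cg{k:06d}"
            k += 1
            if j % 2 == 0:  # inside the gene body
                pos = int(rng.integers(row["start"], row["end"]))
            else:  # within 10 kb of the TSS
                pos = int(row["tss"] + rng.integers(-9000, 9001))
            m = float(rng.uniform(0.15, 0.7))
            cpg_rows.append((cid, row["chrom"], pos, gid))
            means.append(m)
            shifted.append(gene_dmg and j < config.n_shifted_cpgs)
    coords = pd.DataFrame(
        cpg_rows, columns=["cpg", "chrom", "pos", "gene"]
    ).set_index("cpg")
    means = np.asarray(means)
    shifted = np.asarray(shifted)

    n_cpg = len(coords)
    mean_mat = np.tile(means[:, None], (1, len(patients)))
    prog_cols = np.arange(n_resp, n_resp + n_prog)
    raised = means[shifted] + config.beta_shift
    if np.any(raised >= 1):
        warnings.warn("beta_shift pushes some means to 1; clipping",
                      stacklevel=2)
    mean_mat[np.ix_(shifted, prog_cols)] = np.clip(raised, 0.01, 0.99)[:, None]
    beta = _beta_draw(rng, mean_mat, config.beta_precision)

    cohort = ClinicalCohort(
        beta=pd.DataFrame(beta, index=coords.index, columns=patients),
        cpg_coords=coords[["chrom", "pos"]],
        outcome=outcome,
    )
    gt = GroundTruth(seed=config.seed, planted_clinical_dmg=set(dmg))
    return cohort, gt


def generate_reference_atlas(
    config: SynthConfig,
) -> tuple[FeatureMatrix, pd.Series, FeatureMatrix, GroundTruth]:
    """Staged reference expression atlas plus matched cell-line profiles.

    A *developmental* gene subset varies linearly with stage position
    (0 = least mature, 1 = most mature). A larger, disjoint *source* gene
    subset separates reference samples from cell lines, so the
    developmental signal is deliberately not the leading variance
    component. Cell lines are placed at stage positions that decrease with
    resistance rank. Returns (reference matrix, stage positions per
    reference sample, line matrix, ground truth).
    """
    rng = config.rng("atlas")
    series = make_series(config)
    n_genes = config.n_genes
    ids = [f"g{i:05d}" for i in range(n_genes)]
    n_dev = int(round(config.fraction_developmental * n_genes))
    n_src = int(round(config.fraction_source * n_genes))
    perm = rng.permutation(n_genes)
    dev_idx, src_idx = perm[:n_dev], perm[n_dev: n_dev + n_src]

    base = rng.normal(config.baseline_mean, 1.0, size=n_genes)
    dev_load = np.zeros(n_genes)
    dev_load[dev_idx] = config.dev_amplitude * rng.choice([-1.0, 1.0],
                                                          size=n_dev)
    src_load = np.zeros(n_genes)
    src_load[src_idx] = config.source_offset * rng.choice([-1.0, 1.0],
                                                          size=n_src)

    stage_pos = np.linspace(0.0, 1.0, config.n_stages)
    ref_cols, ref_stage, profiles = [], [], []
    for si, t in enumerate(stage_pos):
        for r in range(config.atlas_replicates):
            ref_cols.append(f"stage{si + 1:02d}_rep{r + 1}")
            ref_stage.append(t)
            profiles.append(base + dev_load * t + src_load)
    line_pos = {
        s: config.line_stage_start - config.line_stage_step * k
        for s, k in zip(series.sample_ids, series.resistance_rank)
    }
    line_cols = series.sample_ids
    for s in line_cols:
        profiles.append(base + dev_load * line_pos[s])

    mat = np.column_stack(profiles)
    if config.atlas_noise_sd > 0:
        mat = mat + rng.normal(0.0, config.atlas_noise_sd, size=mat.shape)

    index = pd.Index(ids, name="gene_id")
    reference = FeatureMatrix(
        values=pd.DataFrame(mat[:, : len(ref_cols)], index=index,
                            columns=ref_cols),
        value_kind="log2_expression",
    )
    lines = FeatureMatrix(
        values=pd.DataFrame(mat[:, len(ref_cols):], index=index,
                            columns=line_cols),
        value_kind="log2_expression",
    )
    stages = pd.Series(ref_stage, index=ref_cols, name="stage_position")
    gt = GroundTruth(
        seed=config.seed,
        planted_stage_positions={s: float(p) for s, p in line_pos.items()},
    )
    return reference, stages, lines, gt
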