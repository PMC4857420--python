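# Methods

## The model of the experiment

The package analyses a dose-escalation series: one parental cell line and
four sublines (R100–R4000) of strictly increasing drug resistance,
summarised by a resistance rank (0..4) and an EC50 in nM. All feature
ranking is the sample covariance (n−1 denominator) of a feature with one
of these covariates. Covariance, not correlation, is used deliberately:
features are ranked by the magnitude of their change along the series,
not merely its consistency. The default covariate is the rank; the EC50
is available by flag. Ranking against the raw EC50 is dominated by the
large gap between the last two lines, which is why rank is the
cross-layer default while EC50 reproduces the published expression
analysis.

Missing values: expression and methylation features with any missing
sample are excluded from ranking (RRBS coverage gaps should be filtered
upstream with a minimum-coverage rule, default ≥ 5 reads per fragment per
sample). Variant allele frequencies are handled pairwise-complete — a
zero-depth cell drops out of that variant's covariance only.

## Windowed Poisson ChIP test

Per 50-bp bin, the IP count k is tested against a Poisson rate
λ = max(input, pseudocount) · N_IP/N_input with p = P(Pois(λ) ≥ k)
via the regularized survival function. Numerical behaviour: p(0) = 1
exactly, and the survival function is accurate deep into the tail (the
test suite pins it against a partial-sum oracle to 1e-10 relative error
for λ ≤ 50, k ≤ 200).

Two estimator choices the bin test leaves open were made as follows:

* **Pseudocount = 1 input read** before library scaling. Zero-input bins
  otherwise yield λ = 0 and p = 0 for any IP read.
* **Local input averaging.** The promoter-calling layer feeds the test an
  input count averaged over a centred window of 21 bins (~1 kb,
  configurable via `input_smooth_bins`). A raw per-bin input count is as
  noisy as the IP signal itself and makes the nominal p-values strongly
  anti-conservative (measured ~10⁻³ of null bins at p < 10⁻⁶ at the
  default depths, a thousandfold excess); averaging the background over a
  local window is the standard remedy in windowed Poisson callers and
  restores the nominal rate (~0–4 bins per million at the same
  threshold). Setting `input_smooth_bins=1` recovers the raw behaviour.
* **Library scaling** by the ratio of total mapped read counts.

Promoter windows are strand-aware and strictly upstream: [TSS−5000, TSS)
for plus-strand genes, (TSS, TSS+5000] for minus-strand genes, in 0-based
half-open coordinates; windows crossing the chromosome start are clipped
with a warning. A promoter is enriched when ≥ `min_bins` (3) bins reach
p < `tau` (10⁻⁶). Replicates are pooled by default (`replicate_mode=
"pooled"`); `"both"` instead requires the call in every replicate — the
choice is exposed because either is defensible for a two-replicate
design.

### Pattern grouping

Patterns are the exact binary call strings over the ordered conditions;
grouping by pattern is a partition. The default dynamics labeller maps
"11111"→K1, "00000"→K3, and any pattern with 0 in the parental line, at
least one 1 among the first two resistant lines, and 0 in the final line
→K2 (the intermediate line may be in either state, since the loss is
gradual). All other patterns are "other". The mapping of the remaining
2⁵−8 patterns onto three biological groups is not uniquely determined by
the design, so the labeller is a plain function argument that callers can
replace.

## TF targets and enrichment

A gene is a TF target when any binding interval overlaps the closed
window [TSS−5 kb, TSS+5 kb], strand-agnostic (the most permissive reading
of "within 5 kb of the TSS"; `upstream_only` gives the strand-aware
alternative). The universe is all annotated genes by default and is a
parameter. Enrichment p-values are one-sided (enrichment direction) exact
hypergeometric tails; the Haldane 0.5 correction applies only to the
reported odds ratio when a cell is zero, never to the p-value. Raw
p-values are reported in the heat-map tables (floored at 1e-300 before
−log10); a Benjamini–Hochberg column is available but off by default,
matching the published reporting style.

## Clinical arm

Per CpG, a two-sample KS test compares beta values between responders
(n=14) and progressors (n=5), pairwise-complete per site, requiring ≥ 2
patients per group. The p-value is exact (permutation distribution of D)
whenever n1·n2 ≤ 10,000 — always true at 14 vs 5 — and asymptotic
otherwise. Note the exact test is discrete: its true null rejection rate
at p < 0.05 is the largest achievable level below 0.05, which is 0.04747
at 14 vs 5. The calibration tests assert against that level, not against
0.05 itself, plus a hard bound that the rate never exceeds 0.05's
sampling band (no anti-conservative step).

CpGs link to a gene when they fall in the gene body (half-open) or within
10 kb of the TSS (closed boundary); a CpG may link to several genes. TF
binding regions link to genes by the same rule applied to intervals —
deliberately 10 kb here versus 5 kb in the murine target derivation, as
the two analyses define proximity differently; both windows are
parameters. A gene is differentially methylated when ≥ `min_cpg` (2) of
its linked CpGs are significant at α = 0.05 (uncorrected, per the
published screen; a BH mode exists). The differential × target 2×2 table
is tested one-sided by Fisher's exact test over the universe of genes
entering the linking computation.

## Developmental axis

Reference-atlas and cell-line expression matrices are intersected on gene
ids (no imputation), each gene centred and scaled to unit variance
(ddof=1) across all samples jointly, and decomposed by SVD with samples
as observations. No batch correction is applied, matching the published
combined decomposition; a per-source mean-centering option exists for
sensitivity analysis. Component signs are fixed (largest-magnitude
loading element positive) so results are stable across runs and sample
orders; zero-variance genes are dropped with a reported count.

The developmental component maximises |Spearman| between reference scores
and stage order (ties → lowest index with a warning; best |ρ| below a
floor, default 0.5, warns that the axis is unreliable) and is oriented so
mature stages score positive. Line monotonicity is Spearman's ρ between
resistance rank and developmental score with a two-sided exact
permutation p for n ≤ 8 lines.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of each assay with minimal noise
models matched to each data type's support: Gaussian noise on log2
expression, Beta noise (configurable precision) on methylation fractions,
Poisson counts on ChIP bins, binomial allele counts at Poisson depths.
Defaults mirror the study design: a 5-sample series with EC50 endpoints
857 and 3446 nM (interior values 1100/1700/2500 interpolated and
arbitrary), a 14-vs-5 clinical cohort, 13 singleton variant artifacts,
50-bp bins, two ChIP replicates.

Scale and effect defaults are choices, made once for test power and
documented here rather than tuned: 2,000 genes on one synthetic
chromosome (TSSs every 20 kb), 5% planted covarying genes at effect 1.0
log2-unit per rank against noise SD 0.3; promoter groups 150 K1 / 150 K2
/ 100 random-pattern / rest K3 at enrichment fold 4 over a background of
10 reads per bin per replicate; 300 targets per TF with tenfold sampling
weight on planted covarying genes for the planted TF; clinical
differential genes planted at base rate 0.05 with target odds 4 and a
0.25 beta shift on 3 of 4 CpGs per gene; an 8-stage reference atlas with
3 replicates per stage. The within-line biological variance of the real
assays is unknown, so these noise levels say nothing about real-data
power — passing recovery tests demonstrate correctness of the machinery
at the planted signal-to-noise, not sensitivity on real experiments.

Two construction details matter for interpretation:

* The atlas's source component (reference vs cell line) is made
  orthogonal to the stage gradient by placing the lines' developmental
  positions (0.8 − 0.15·rank) so their mean equals the reference stage
  mean (0.5). Without this, a sliver of the developmental trend leaks
  into the larger source component and the two components become
  indistinguishable by rank correlation alone.
* "Other"-group promoters draw their pattern uniformly from the 24
  patterns that the default labeller does not map to K1/K2/K3, so the
  planted grouping and the labeller are consistent by construction.

Every generator is deterministic given (config, seed): each draws from
its own numpy SeedSequence stream keyed by the seed, so layers can be
regenerated independently and byte-identically.

## Problem sizes in the test and acceptance runs

The shipped test suite and acceptance script run the study at a scale
chosen to keep full recovery measurable in minutes on one core: the
default 2,000-gene genome for recovery checks (top-list size 5% of genes,
the published list's proportion of its array), a 10,000-CpG null cohort
for KS calibration, 480,000 null ChIP bins for Poisson calibration, and
20 replicate 400-gene cohorts for the clinical odds-ratio estimate.

## Known limitations

* The bin test conditions on the (smoothed) input count rather than
  modelling its sampling variance; a gamma-Poisson treatment would be
  more exact at low input depth.
* Exact KS p-values assume exchangeability and are computed by scipy's
  path-counting; with heavily tied beta values the permutation
  distribution conditions on the observed ties only through D itself.
* The combined PCA applies no cross-platform normalisation beyond
  per-gene standardisation; real atlas integrations usually need more.
* The synthetic genome is a single chromosome with evenly spaced,
  non-overlapping genes; linking edge cases from nested or overlapping
  real gene models are exercised only in unit tests, not by the
  generator.
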