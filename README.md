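# resistaxis

Integrative analysis of acquired drug resistance in a dose-escalation
cell-line series, across four molecular layers plus a clinical cohort.

The setting: a drug-sensitive parental lymphoma line and a series of
increasingly resistant sublines (Parental, R100, R500, R1000, R4000)
derived by alkylating-agent dose escalation, profiled for gene expression,
CpG methylation (RRBS fragments), H3K27me3 occupancy (ChIP-seq) and DNA
variants. The package implements the analyses that connect these layers to
the resistance phenotype, and a synthetic-data generator that emulates all
of the inputs with planted, recoverable structure so every method can be
validated end to end.

## What it computes

**Covariance ranking.** For each feature x (log2 expression, fragment
methylation, or variant allele frequency) and resistance covariate c
(series rank 0..4, or EC50 in nM), the sample covariance

&nbsp;&nbsp;&nbsp;&nbsp;cov(x, c) = Σᵢ (xᵢ − x̄)(cᵢ − c̄) / (n − 1)

ranks features by how strongly they track resistance; the extreme top and
bottom lists (default size 1000) feed the enrichment analyses. Variant
screening adds a flag for alleles observed in exactly one sample, a
signature of sequencing artifacts in serial designs.

**ChIP enrichment and promoter dynamics.** Each 50-bp bin is tested by an
upper-tail Poisson test of the IP count against the library-scaled local
input rate, λ = max(input, pseudocount) · N_IP/N_input, p = P(Pois(λ) ≥ k).
A promoter (5 kb strictly upstream of the TSS, strand-aware) is *enriched*
in a condition when ≥ 3 bins reach p < 10⁻⁶. Binary calls across the five
ordered conditions form a pattern string ("01100", ...) grouped
combinatorially and labelled: K1 = marked throughout, K2 = rapid gain at
low doses then loss, K3 = never marked. Metagene profiles average
log2((IP+1)/(scaled input+1)) around TSSs of a gene set.

**TF-target enrichment.** A gene is a TF target when a binding site
overlaps ± 5 kb of its TSS. Gene lists are tested for target enrichment by
the one-sided Fisher's exact test (upper hypergeometric tail); a heat-map
table of −log10 p over TFs × lists summarises the regulators.

**Clinical methylation arm.** In a cohort of 14 responders vs 5
progressors, each CpG's beta values are compared by a two-sample
Kolmogorov–Smirnov test (exact p at these group sizes). CpGs link to genes
in the gene body or within 10 kb of the TSS; genes with ≥ 2 significant
linked CpGs are flagged differentially methylated, and the differential ×
TF-target 2×2 contingency is tested one-sided by Fisher's exact test.

**Developmental axis.** Cell-line and reference-atlas expression profiles
are decomposed jointly by PCA on unit-variance genes; the component whose
reference scores best track the known maturation stages (max |Spearman|)
is the developmental axis, and the resistant lines' scores along it are
tested for monotonicity in resistance rank by exact permutation.

## Worked example

```python
from resistaxis import SynthConfig, RunConfig, run_pipeline

cfg = RunConfig(synth=SynthConfig(seed=1), top_size=100, seed=1)
summary = run_pipeline(cfg, "out/")
print(summary)
```

```
{'seed': 1, 'top_gene_recall': 1.0, 'singleton_artifacts_flagged': 13,
 'promoter_label_recovery': 1.0, 'planted_tf_is_max': True,
 'tf_target_derivation_exact': True, 'clinical_odds_ratio': 3.072,
 'clinical_p_value': 3.71e-09, 'clinical_dmg_recall': 1.0,
 'developmental_pc': 2, 'monotonicity_rho': -1.0}
```

Reading the output: every planted resistance-covarying gene was recovered
in the matched-size top-covariance list (`top_gene_recall`); all 13
planted single-sample variant artifacts were flagged; every planted
K1/K2/K3 promoter received its dynamics label; the planted TF had the
strongest enrichment over the high-covariance list; the clinical
contingency recovered an odds ratio of 3.1 against a planted target odds
of 4 at p ≈ 4·10⁻⁹; and the developmental signal was identified on the
second principal component with the resistant lines perfectly
anti-ordered along it (Spearman ρ = −1), i.e. more resistant lines sit at
less mature positions. The same stages are available individually from
the command line (`resistaxis simulate|rank|chip|tfenrich|clinical|axis|run`).

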