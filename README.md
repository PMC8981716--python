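# rnadx

RNA-seq outlier diagnostics for Mendelian disease.

When exome sequencing of a rare-disease patient comes back inconclusive, a
single RNA-seq assay of patient fibroblasts can expose the functional
consequence of the variant that was missed: a gene expressed far outside its
cohort distribution, an intron spliced at the wrong site, or a heterozygous
variant expressed from only one allele.  `rnadx` implements the statistical
core of that diagnostic workflow for clinical and research cohorts:

* **Aberrant expression** — per-gene negative binomial outlier test,
  NB(μ<sub>ij</sub>, θ<sub>i</sub>) with Var = μ + μ²/θ, after size-factor
  normalisation and a deterministic rank-q latent-factor correction (truncated
  SVD of centred log counts); BH FDR per sample; effect size = observed /
  expected fold change; gene dispersion reported as the biological coefficient
  of variation BCV = 1/√θ.
* **Aberrant splicing** — annotation-free percent-spliced-in metrics ψ₅, ψ₃
  and splicing efficiency θ\_splice, tested per (junction, sample) against a
  beta-binomial null with per-junction intra-class correlation; genes gated by
  Holm FWER < 0.1 across their junctions, outlier junctions by FDR < 0.1 and
  |Δψ| > 0.3.
* **Mono-allelic expression (MAE)** — negative binomial test of the allelic
  ratio at heterozygous SNVs with ≥ 10 reads (exact NB tail test and an NB
  Wald test on ln(alt/ref); Wald is the calling default); significant iff
  FDR ≤ 0.05 and allelic imbalance > 0.8.
* **RNA variant filtering** — GATK-style hard filters (QD < 2, FS > 30,
  3 SNVs / 35 bp cluster), repeat-mask and alt-read prioritisation, and a
  het/hom precision–recall benchmark against a truth set.
* **Cohort statistics** — Fisher association of outlier classes with rare-
  variant consequence groups (Clopper–Pearson intervals), gene-class
  enrichment by pairwise logistic regression, potential-PTV flagging.
* **Power analysis** — recall of injected outliers versus mean expression,
  BCV and fold change, and MAE recall versus allelic coverage.
* **Triage** — the diagnostic decision flow (diagnosed / VUS-followup /
  research-candidate / unlikely) and case-table summarisation.

Every stage is drivable from a synthetic-cohort generator
(`rnadx.simulate`) that produces NB counts with latent batch structure,
beta-binomial junction usage, overdispersed allelic counts and annotated
variant tables — together with ground-truth tables, so detection recall is
measurable without patient data.

## Worked example

Simulate a cohort of 80 fibroblast samples, inject underexpression outliers
at fold change 0.2 (one random sample per gene, in batches of 300 genes),
and call outliers:

```python
from rnadx import (CohortConfig, ExpressionOutlierModel,
                   inject_expression_outliers, simulate_counts)

cfg = CohortConfig(n_samples=80, n_genes=1000, seed=7)
matrix, annotation, _ = simulate_counts(cfg)
injected, truth = inject_expression_outliers(matrix, [0.2], 300, seed=7)

res = ExpressionOutlierModel(injected, q=2).fit()
print(res.summary())
print(res.calls(fdr_cutoff=0.05).head())
```

```
Expression outlier model
==============================================
genes                 1000
samples               80
latent rank q         2
median dispersion     18.6
median BCV            0.232
calls at FDR<=0.05    680
median calls/sample   8.0

sample   gene           class      p_value          fdr  effect_size   z_score
 S0070 G00239 underexpression 6.316723e-14 6.316723e-11     0.197350 -7.945841
 S0001 G00294 underexpression 1.989872e-13 1.989872e-10     0.242450 -7.697310
 S0016 G00467 underexpression 2.209291e-13 2.209291e-10     0.165661 -7.902006
```

677 of the 1000 injected five-fold reductions are recovered among the 680
calls at FDR ≤ 0.05
(the remainder sit in weakly expressed or highly dispersed genes — exactly
the regime the power module quantifies); the reported effect sizes cluster
around the injected 0.2, and each call carries its p-value, per-sample FDR
and log-scale z-score.  On clean null cohorts the same model calls a median
of 0–2 outliers per sample.

A thin CLI mirrors the library (`rnadx simulate`, `rnadx qc`,
`rnadx aberrant-expression`, `rnadx aberrant-splicing`, `rnadx mae`,
`rnadx rna-variants`, `rnadx power`, `rnadx triage`, `rnadx report`).

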