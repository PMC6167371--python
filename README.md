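# immunosubtype

Gene-expression-based immune subtyping of bulk tumor RNA-seq cohorts,
with the tumor micro-environment quantifications the subtypes rest on.

Non-small-cell lung cancers (and solid tumors generally) split into an
**immune-deficient Subtype A** and an **immune-competent Subtype B**:
B-tumors carry heavy stromal and immune infiltration, cluster with
adjacent noncancer tissue in expression space, and show elevated immune
checkpoint expression — the population most relevant to checkpoint
blockade. This package implements that classification and its
supporting analyses as a reusable, testable pipeline for anyone working
with tumor/normal count matrices: simulation of ground-truth cohorts,
normalization, subtyping, differential expression, enrichment,
micro-environment scoring, immune deconvolution, signature z-scores,
group statistics and survival.

## The method

Starting from a raw gene × sample count matrix with tumor/normal labels:

1. **Normalization** — median-of-ratios size factors; a shifted-log
   variance-stabilizing transform `log2(count/sf + 1)` for clustering;
   FPKM and log2 median-centered FPKM for scoring.
2. **Micro-environment scores** — per-sample rank-weighted running-sum
   enrichment (ssGSEA-style, weight `rank^0.25`) of stromal and immune
   signatures; their sum is the combined score, mapped to tumor purity by
   `purity = cos(0.6049872018 + 0.0001467884 · score)`; the cytolytic
   score is the geometric mean of GZMA and PRF1 FPKM.
3. **Subtyping** — PCA of tumors *and* normals on the top 1,000
   most-variable genes, k-means with k = 3 (Ward 3-cut as a concordance
   diagnostic); the cluster holding most normals is "normal-like" and its
   tumors are called B; of the other two clusters the higher mean tumor
   immune score is B, the lower is A; normals are `noncancer`.
4. **Differential expression** — per-gene negative-binomial Wald test
   (method-of-moments dispersion) of B vs A, Benjamini–Hochberg
   adjustment, and the filter *adjusted p < 0.05, |log2FC| ≥ 1,
   baseMean ≥ 100*.
5. **Enrichment** — hypergeometric over-representation of the A-UP/B-UP
   lists in GMT gene sets; sets passing p < 0.05 and q < 0.1 ranked by
   −log2(q), top 10 reported.
6. **Deconvolution** — abundances of six immune cell types (B, CD4+ T,
   CD8+ T, neutrophil, macrophage, dendritic) by non-negative least
   squares on reference profiles over purity-filtered marker genes.
7. **Signature z-scores** — per gene,
   `z = (FPKM_tumor − mean FPKM_normals) / sd FPKM_normals`, averaged
   over signature panels (M1/M2, B-reg, activated/normal stroma, immune
   checkpoints).
8. **Statistics** — Shapiro-Wilk-gated t/Mann-Whitney (or
   ANOVA/Kruskal-Wallis), Pearson correlation, Kaplan-Meier curves with
   a log-rank test, and subtype bookkeeping tables.

A seeded synthetic-cohort generator provides ground truth for all of
this: tumors are purity-weighted mixtures of a malignant profile plus
stromal and immune cell profiles with negative-binomial count noise,
immune-competent tumors drawing stochastically lower purity.

## Worked example

```python
from immunosubtype import ImmuneSubtypeModel, make_reference_panel, simulate_cohort

panel = make_reference_panel(n_genes=2000, seed=7)
cohort = simulate_cohort(panel, seed=7)          # 40 A + 40 B tumors, 40 normals
results = ImmuneSubtypeModel.from_cohort(cohort).fit(seed=7)
print(results.summary())
```

```
Immune subtyping results
========================
samples: 80 tumors, 40 normals; 2000 genes
PCA on top 1000 variable genes: PC1 32.3%, PC2 10.1%, PC3 3.5%
k-means/Ward agreement (ARI): 1.000
  Subtype A: 40/80 (50.00%)
  Subtype B: 40/80 (50.00%)
DEGs (adj p < 0.05, |log2FC| >= 1.0, baseMean >= 100): 96 (47 B-UP, 49 A-UP)
mean scores (A vs B): stromal: 101 / 179; immune: 86 / 154; purity: 0.807 / 0.794; cyt: 178 / 223
log-rank A vs B: chi2 = 2.721, p = 0.0991
```

Reading the output: the three PCs separate tumors from normals; k-means
and Ward agree perfectly on the 3-way split; all 80 tumors are assigned,
and the called B group shows the expected micro-environment pattern —
higher stromal/immune/cytolytic scores and lower estimated purity than
A. The 96 genes passing the DEG filter are the planted subtype contrast
(the generator plants 100, a handful fall under the baseMean or fold
filter after purity attenuation), and survival does not differ between
subtypes because the generator simulates it independently of subtype by
default. `results.scores`, `results.fractions`, `results.deg_table`,
`results.signature_z` etc. hold the per-stage tables;
`results.save("outdir")` writes them all as TSV with a JSON manifest.

The same workflow is available from the shell:

```bash
immunosubtype simulate --out cohort_dir --seed 7
immunosubtype run --cohort-dir cohort_dir --out results_dir --seed 7
```

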