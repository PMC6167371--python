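# Methods

This note documents the models and procedures implemented in
`immunosubtype`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## The synthetic cohort model

Each bulk sample is a convex mixture of nine population profiles:
malignant, activated stroma, normal stroma, and six immune cell types
(B, CD4+ T, CD8+ T, neutrophil, macrophage, dendritic).

* **Reference panel.** Baseline per-gene means are log-normal
  (log-mean log 20, σ = 1.2 — a right-skewed FPKM-like distribution).
  Each population owns a disjoint block of marker genes elevated
  `fold` = 8× in that population only (default 100 markers per
  population among 2,000 genes). Two CD8+ T markers are named GZMA and
  PRF1 so the cytolytic score is defined. Gene lengths are uniform in
  [500, 5000] bp so the FPKM length correction is exercised
  nontrivially.
* **Composition.** Tumor purity is Beta(18, 4) for the immune-deficient
  subtype A (mean 0.82) and Beta(8, 8) for the immune-competent subtype
  B (mean 0.50); normals have purity 0. The non-malignant remainder is
  split by a Dirichlet over the eight other populations — tumors
  (2, 1, 1, 1.5, 1.5, 1, 1.5, 0.5), normals
  (1.5, 3, 1.5, 2, 2, 1.5, 2, 1) in the population order above — i.e.
  normals carry more normal stroma and lymphocytes, as adjacent normal
  lung does. These concentrations are the package's own choice of a
  realistic regime (purity distributions of the real cohorts are not
  published); B's higher infiltration follows from its lower purity, not
  from a different immune composition.
* **Counts.** Expected counts scale the mixture mean by gene length and
  a log-normal library size (mean 2×10⁶ reads, σ = 0.2); observed counts
  are negative binomial with one global dispersion (default 0.1), the
  same model the differential test assumes. In the small-dispersion,
  deep-library limit FPKM converges to the mixture means.
* **Planted differential signal.** 100 malignant-profile genes carry a
  planted A-vs-B contrast of `de_lfc` = 2 log2 units, applied
  symmetrically (up genes ×2^(+1) in B and ×2^(−1) in A; down genes
  reversed), alternating up/down along decreasing malignant expression,
  with each subtype's planted genes rescaled to exactly baseline total
  mass. The symmetric, mass-neutral construction keeps the planted fold
  change near ±2 and — importantly — leaves both subtypes' library
  composition untouched, so unplanted genes' FPKM is not perturbed as a
  side effect. Because the planted shift lives in the malignant
  compartment, the *observed* fold change is attenuated by purity
  mixing (≈ ±1.3 at the default purities); a planted down-shift on a
  gene the infiltrate also expresses cannot exceed |log2FC| ≈ 0.7 at
  purity 0.5, which is why a few of the 100 planted genes fall under
  the |log2FC| ≥ 1 filter.
* **Survival.** Exponential times (scale 60), administratively censored
  at 120, independent of subtype by default — the null regime — with a
  `hazard_ratio` knob for power studies of the log-rank code.
* **Determinism.** Everything derives from one root seed;
  regeneration is bit-identical. Benchmark replicates draw child seeds
  from a `SeedSequence`.

**What the generator does not emulate:** batch effects between cohorts,
gene-gene correlation beyond the mixture structure, isoform/length
biases, dropout, subtype-specific immune composition, or marker genes
shared between populations. Marker genes retain full baseline expression
in all other populations (they are 8× elevated, not exclusive), which
caps immune-marker fold changes between subtypes at ~1.3× — smaller than
in real immune-competent tumors. Passing tests therefore demonstrate
correctness of the machinery and recoverability under a known mixture
model, not performance on real cohorts.

## Normalization

Size factors are median-of-ratios: the median over all-sample-expressed
genes of count/geometric-mean (median taken in linear space). The
variance-stabilizing transform is `log2(count/sf + 1)` — a shifted-log
approximation of the parametric DESeq-style VST. Its downstream use is
only variance ranking and PCA geometry, which the shifted log preserves;
the exact parametric fit is deliberately out of scope. FPKM is
`count·10⁹/(library·length)`; the log2 median-centered form uses
pseudocount 1 (configurable; no value is published for this chain).
"Most variable" genes are ranked by variance (the conventional reading),
ties broken lexicographically for determinism.

## Subtyping

PCA (3 components, full SVD, sign fixed so each component's
largest-magnitude loading is positive) on tumors and normals jointly
over the top 1,000 variable genes; k-means k = 3 with 50 seeded restarts
(making the best-inertia solution reproducible), plus a Ward 3-cut whose adjusted Rand agreement with
k-means is reported as a stability diagnostic. The subtype rule is the
algorithmic form of "B co-clusters with normals and is immune-enriched":
(i) the cluster with the largest normal fraction is normal-like and its
tumors are B; (ii) of the remaining two clusters the higher mean tumor
immune score is B, the other A; ties on normal fraction break toward
the higher immune score. With no normals at all the rule degrades to
immune-score ranking of all three clusters (middle cluster joins the
nearer mean) and the result is flagged. 95 % confidence ellipsoids are plot decoration only and play no
role in assignment.

## Micro-environment scores

The single-sample enrichment statistic walks a sample's genes by
decreasing expression rank; in-set steps add `rank^α` (α = 0.25, the
published weighting) normalized over the set, out-of-set steps subtract
`1/(N − m)`, and the score is the sum of the running-sum deviations.
Two consequences worth stating: the score depends on ranks only (any
per-sample monotone transform gives identical scores), and a *random*
gene set has positive expected score ≈ 0.056·N at α = 0.25 — the rank
weighting front-loads in-set mass — which matches the score scale the
published purity transform assumes. The degenerate all-genes signature
is defined as score 0. Purity is
`cos(0.6049872018 + 0.0001467884·(stromal + immune))`, the published
closed form, clipped to [0, 1] (clipping added, since the
cosine leaves [0, 1] for extreme scores). The cytolytic score is the
geometric mean of GZMA and PRF1 FPKM with offset 0.01 (the published
convention for handling zeros).

## Differential expression

Per-gene dispersion is method-of-moments on size-factor-normalized
counts, pooled across the two groups and floored at 10⁻⁸; the Wald
statistic is the log2 difference of group means (pseudocount 0.5) over a
plug-in NB delta-method standard error, referred to a t distribution
with nA + nB − 2 degrees of freedom. The t reference (rather than
normal) absorbs the extra variability of the moment dispersion estimate
at small n; under the null simulation (dispersion 0.1, n = 10 vs 10) the
empirical type-I error at nominal 0.05 is ≈ 0.06. Dispersion shrinkage
across genes is deliberately omitted: at the baseMean ≥ 100 filter the
simple estimator is adequate, as the calibration and power harnesses in
the test suite verify. Filter boundary semantics:
adjusted p strictly < 0.05, |log2FC| ≥ 1 and baseMean ≥ 100 inclusive.

## Enrichment

Over-representation is the hypergeometric upper tail P(X ≥ k) of the
overlap, with the universe equal to all genes tested for differential
expression (the standard conservative choice). BH q-values are computed across sets; reporting keeps
sets with p < 0.05 and q < 0.1, ranked by −log2(q), ties broken by
smaller raw p then name. Ranked-list (KS-statistic) GSEA and GO DAG
propagation are out of scope; gene sets are plain GMT inputs.

## Deconvolution

"TIMER-style" means: discard marker genes whose Spearman correlation
with estimated purity exceeds 0 (they track the malignant compartment),
relaxing the threshold in 0.1 steps with a warning if a cell type would
drop below 5 genes; then decompose each sample's linear-scale expression
on the six reference profiles by non-negative least squares after
scaling each gene by the across-type standard deviation of the
reference. NNLS on purity-filtered markers is a defensible, testable
estimator with ground-truth recovery; it is not TIMER's
per-type partial-regression procedure. Coefficients are reported raw
and simplex-normalized (proportions among the immune compartment;
simplex mode is invariant to global rescaling of a sample's
expression). On default synthetic cohorts per-type recovery
correlations are ~0.9 (weakest for the rarest population, dendritic
cells, whose markers are also the ones most often lost to the purity
filter through bulk composition effects).

## Signature z-scores

`z = (x − mean(normals)) / sd(normals)` per gene on linear FPKM, exactly
as the defining equation states (an optional log2 mode exists, off by
default). The control SD uses the n−1 denominator; genes with zero
control SD are excluded and recorded. Panel scores are unweighted means
over the signature's valid genes. The checkpoint registry ships PD-1,
PD-L1, PD-L2, CTLA4, B7-1, B7-2, Tim-3, Galectin-9; the Tim label is
configurable (some published gene lists print "Tim-2" where
Tim-3 is almost certainly meant — the registry does not silently
correct, it parameterizes).

## Group statistics and survival

Comparisons gate on Shapiro-Wilk at α = 0.05 per group (the
conventional gate level): all groups normal → t test / one-way ANOVA,
otherwise Mann-Whitney U / Kruskal-Wallis; all tests two-sided; groups
need n ≥ 3. Constant data short-circuits to p = 1. Pearson correlation
uses the t-based two-sided p. Survival uses the Kaplan-Meier
product-limit estimator and the two-group log-rank test (lifelines),
verified in the tests against a hand O−E/V tally. Bookkeeping
percentages round half-up to two decimals (48/87 → 55.17).

## Problem sizes and determinism of the reported numbers

The recovery benchmark simulates 20 cohorts of 80 tumors + 40 normals ×
2,000 genes (the default conditions) and refits the full pipeline per
cohort; the null calibration uses 20 replicates of 2,000 genes at
n = 10 vs 10. These sizes make the whole suite and the acceptance script
run in seconds while leaving all recovery margins wide. All randomness
flows from explicit seeds; per-replicate seeds are drawn from a
`SeedSequence` of the root seed.

## Known limitations

* The VST is a shifted log, not the parametric variance-stabilizing
  fit; do not reuse it where the exact VST's mean-variance profile
  matters.
* ssGSEA scores are on the raw-rank scale of the input matrix's gene
  count; the purity cosine transform was calibrated for genome-scale
  rank sums, so on small simulated panels the purity *ranking* is
  reliable while its absolute level is compressed.
* The NB test has no dispersion shrinkage and is mildly anticonservative
  (type-I ≈ 0.06 at nominal 0.05, n = 10 per group).
* Subtype assignment assumes exactly three clusters; cohorts whose
  structure is not tumor/normal-like may need a different k and rule.
* The generator's marker model (elevated, not exclusive) understates
  immune-gene fold changes between subtypes; end-to-end DEG lists on
  synthetic cohorts contain the planted malignant-profile contrast, not
  immune genes.
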