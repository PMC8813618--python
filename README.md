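# mkmeta — cross-cohort multi-kingdom microbiome meta-analysis

Gut-microbiome biomarkers for a disease rarely survive the trip from one
patient cohort to another: technical batch effects, geography and diet shift
taxon abundances more than the disease does.  `mkmeta` implements the
cross-cohort analysis stack used for multi-kingdom (bacteria, fungi, archaea,
viruses) metagenomic case/control studies, end to end and fully testable on
synthetic data with known ground truth:

* **Differential abundance across cohorts** — relative abundances are
  arcsine-square-root transformed (`y = arcsin √p`), cohort batch effects are
  removed with a zero-preserving empirical-Bayes location/scale adjustment
  (ComBat-style), a covariate-adjusted linear model
  `y ~ group + age quartile + sex + BMI class` is fitted per cohort, and the
  per-cohort group coefficients β_k are pooled by inverse-variance fixed
  effects: β̂ = Σw_kβ_k / Σw_k with w_k = 1/se_k², heterogeneity summarized by
  Cochran's Q and I² = max(0, (Q − df)/Q)·100, multiplicity by
  Benjamini–Hochberg FDR.
* **Marker selection** — Boruta-style shadow-feature selection (random-forest
  importance vs. per-iteration permuted shadow copies, binomial decision rule
  with Bonferroni correction) followed by a greedy collinearity filter that
  keeps only features with pairwise |r| < 0.7.
* **Diagnostic models** — random forests evaluated by 20×5-fold stratified
  cross-validation with inner-loop tuning, 1,000-permutation model
  significance (plus-one rule, p ≥ 1/1001), cohort-to-cohort transfer,
  leave-one-cohort-out (LOCO) validation, rank-aggregated Gini importance and
  an incremental minimal-panel procedure, plus external-cohort validation,
  non-target-disease specificity and early-stage evaluation.
* **Co-abundance meta-networks** — SparCC/FastSpar-style compositionality
  corrected correlations (log-ratio variances t_ij = var ln(x_i/x_j), basis
  variances from the sparsity-approximation linear system, 20 exclusion
  refinement iterations), per-cohort permutation p-values, Fisher combination
  (−2Σln p ~ χ²_2k) with median magnitude across cohorts, gated at
  FDR < 10⁻⁵ and |median r| > 0.3 (fair) / 0.6 (moderate) tiers.
* **Ecology & function** — Shannon/Simpson alpha diversity, Bray–Curtis
  distances, PCoA, seeded PERMANOVA (999 permutations), gene-to-pathway
  aggregation and flat species–function Spearman screens.
* **Synthetic studies** — a multi-cohort, multi-kingdom compositional count
  generator with planted markers, batch shifts, covariate confounding,
  Gaussian-copula correlation blocks and structural zeros, so every stage's
  behaviour can be scored against known truth.

## Worked example

The bundled demo configuration simulates 5 cohorts × 60 samples over 4
kingdoms × 100 features with planted markers and correlation blocks, then
runs the full pipeline (a couple of minutes on one CPU):

```python
from mkmeta import demo_config, run_pipeline

results = run_pipeline(demo_config(seed=1, out_dir="demo"))
print(results["report"])
```

or equivalently `mkmeta run --seed 1 --out demo`.  The report printed for
seed 1 includes:

```
- PERMANOVA group:  R2=0.0087  p=0.005
- PERMANOVA cohort: R2=0.0695  p=0.005
- features tested: 399; called: 58 ({'archaea': 14, 'bacteria': 17, 'fungi': 14, 'viruses': 13})
- planted markers tested: 32; recall=1.000, precision=0.552
| bacteria                       | 10 | 0.968 |
| bacteria+fungi+archaea+viruses | 36 | 0.996 |
- panel: 12 features, CV AUROC 0.988, permutation p 0.02
- mean cohort-to-cohort AUROC: 0.966; mean LOCO: 0.985
```

Reading the numbers: cohort identity explains far more community variance
(R² = 0.07) than disease status (R² = 0.009), yet both are significant at the
permutation floor; the differential meta-analysis recovers every planted
marker (recall 1.0) at p < 0.05; combining all four kingdoms beats any single
kingdom's model (0.996 vs ≤ 0.968 mean CV AUROC); and pooled-cohort training
(LOCO 0.985) transfers better than single-cohort training (0.966), the
pattern that motivates cross-cohort marker discovery.  The demo's permutation
p-value of 0.02 is the plus-one floor at its reduced 49-permutation budget —
at the full 1,000 permutations the floor is ~0.001.

Individual stages are available as library functions
(`mkmeta.metadiff.meta_differential_abundance`,
`mkmeta.featselect.boruta_select`, `mkmeta.networks.sparcc_correlations`, …)
and as CLI subcommands (`mkmeta simulate|diversity|diffabund|select|network|run`).

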