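# Methods

This note documents the statistical models implemented in `mkmeta`, the
synthetic-data generator the tests score against, and the numerical and
design choices made where several defensible options existed.

## Synthetic multi-cohort studies

`mkmeta.synthdata.generate_study` draws a study as follows.  Per-feature
baseline log-abundances are `N(0,1)` plus an `Exp(1.5)` right tail, giving a
few dominant taxa and many rare ones, as in real metagenomes.  Sample-level
log-abundance deviations (SD 1.0) are drawn through a Gaussian copula whose
correlation matrix is the identity outside the user's requested blocks, so
planted associations are linear on the log scale — exactly the regime the
compositionality-corrected correlation estimator assumes, which makes the
copula an analytic oracle for network recovery.  Cohort batch shifts are
`N(0, batch_sd²)` per cohort × feature; signed marker effects (magnitude
`marker_log_fold_effect`, sign random per marker) are added to case samples;
age (uniform 30–80, +2 years in cases as mild confounding), sex
(Bernoulli 0.5) and BMI (`N(24, 3²)`) affect a random 10% of features with
`N(0, covariate_effect_sd²)` coefficients.  Log-abundances are exponentiated
and closed to a composition; independent Bernoulli dropout (rate
`zero_inflation`) is applied *before* counts are drawn, mimicking
detection-limit (structural) zeros rather than sampling zeros; counts are
multinomial at a `Poisson(library_size_mean)` library size drawn per sample.
All kingdoms share one multinomial, so per-kingdom tables are slices of a
single composition and kingdom row sums add up to the library size.

What the generator does **not** emulate: phylogenetic structure, strain-level
variation, sequencing-run artefacts beyond a per-cohort log shift,
non-linear covariate effects, and longitudinal sampling.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not performance on any particular real cohort.

Cases are additionally flagged `early`/`advanced` (fraction
`early_stage_fraction`, default 0.5); `early_effect_scale` (default 1.0)
scales the marker effect in early-stage samples so the early-stage
evaluation can be exercised with attenuated signal.

## Differential abundance

Counts → relative abundance → `arcsin √p` (variance-stabilizing for
proportions; zeros map to exactly 0, no pseudo-count).  Batch correction is
a ComBat-style empirical-Bayes location/scale adjustment on the transformed
scale: standardize each feature against a covariate-adjusted grand model,
shrink per-batch means (normal prior) and variances (inverse-gamma prior,
method-of-moments hyperparameters, iterated to convergence), restore the
grand location/scale.  Two deliberate departures from the classical
formulation: entries that were exactly zero stay exactly zero (an absence
must not become a presence), and adjusted values are clipped at 0 to keep
the abundance scale meaningful.  Correction happens on the transformed
scale, before modeling.

Within each cohort an OLS fit of the adjusted abundance on case/control
status plus discretized covariates gives the group coefficient and standard
error.  Covariates enter as discrete variables: within-cohort age quartiles
(rank-based, robust to ties) and BMI classes lean < 25,
overweight (25, 30], obese > 30 (the conventional cut-offs; a "lean (> 25)"
label occasionally seen in clinical metadata contradicts the adjacent
overweight interval and is treated as a typo, with a warning).  Per-cohort effects are pooled by
inverse-variance fixed effects; the pooled z is referred to the normal, Q
and I² summarize heterogeneity, BH controls FDR.  The default candidate
gate is raw p < 0.05, with the FDR gate exposed as an option.  Fold change
is log2 of case-vs-control mean relative abundance with a 1e-6 pseudo-count,
reported descriptively alongside the model-based effect.

Calibration caveat: the pooled normal-theory p is mildly anti-conservative
(per-cohort statistics are t-distributed with ~50 df, and skewed residuals
add a little), and the compositional closure couples features so the
false-positive *rate of a single study* is heavy-tailed across simulations.
The calibration tests therefore average the p < 0.05 rate over replicate
null studies, and switch covariate effects off in the null so that no
genuine group signal leaks in through the planted age–disease confounding
(quartile adjustment removes that confounding only coarsely — which is a
property of the field's covariate-discretization convention, not a bug).

## Feature selection

The shadow-feature (Boruta-style) loop appends one independently permuted
copy of every surviving feature per iteration, fits a random forest, and
scores a hit for real features whose Gini importance exceeds the *maximum*
shadow importance.  Hits vs. runs are tested binomially at 0.5, Bonferroni
corrected across still-undecided features (the `mcAdj` convention);
confirmation and rejection use the one-sided tails.  There is no
tentative-rough-fixing pass: features still tentative at the iteration cap
are excluded from candidates.  Defaults mirror the reference R
implementation (α = 0.05, cap 1000 iterations); tests and the demo use
reduced caps since decisions stabilize within tens of iterations at these
problem sizes.  A known property of the shadow construction: a noise
feature that is correlated with the labels *in-sample* keeps that
correlation across iterations while shadows lose it, so occasional false
confirmations are expected (about one per run at n = 60, p = 40 in the null
tests).

The collinearity filter is a greedy pass in descending importance order
keeping features whose absolute Pearson correlation with every kept feature
stays below 0.7, computed on the same arcsine-sqrt scale the models see.
Greedy keep-by-importance makes the rule deterministic and favours
informative features.

## Diagnostic models and evaluation

The learner is scikit-learn's random-forest classifier; scores are class
vote fractions, AUROC is the Mann–Whitney statistic with half-credit ties.
Repeated stratified CV (default 20×5) optionally tunes
`max_features ∈ {√p, p/3}` × `min_samples_leaf ∈ {1, 5}` by inner 3-fold
AUROC *inside each training split* — no test row ever reaches the tuner or
fitter, and a canary test plants a leak to confirm the guard.  Permutation
significance recomputes the mean CV AUROC under label permutation with the
plus-one rule, flooring at 1/(B+1); with B = 1000 a strong signal reports
p ≈ 0.001.  Null CV AUROC has the well-known small-sample pessimistic bias
(≈0.44 at n = 80), which recedes by n = 200 — the calibration tests use the
larger size.  Cohort-to-cohort transfer trains on one whole cohort and
scores another; LOCO trains on the pooled remainder.  Gini importances are
rank-aggregated across cohorts (mean within-cohort rank, ties by mean raw
importance, then id), and the incremental panel adds features in rank order
until the mean CV AUROC is within ε = 0.001 of its maximum, choosing the
smallest such size.  Early-stage evaluation keeps controls plus early
cases and down-samples the majority class inside every training fold
(seeded); the LOCO variant trains on the pooled remainder without
rebalancing.

## Co-abundance networks

Fractions are single Dirichlet posterior means `(count+1)/(rowsum+D)` — a
deterministic choice in place of the original bootstrap averaging over
Dirichlet draws, which makes every downstream p-value reproducible.  With
t_ij = var ln(x_i/x_j) (sample variance), the sparsity approximation
t_ij ≈ ω_i² + ω_j² yields a linear system for basis variances whose
no-exclusion solution is the closed form ω_i² = (t_i − W)/(D−2),
W = Σt_i/(2D−2); the implementation always solves the system exactly, which
generalizes seamlessly when pair exclusions change per-feature degrees.
Refinement excludes the strongest |ρ| pair above 0.1 (the FastSpar default
threshold) for up to 20 iterations; features left with < 3 partners are
frozen at their last estimate; basis variances are floored at 1e-8 with a
warning.  D ≥ 4 features and n ≥ 10 samples are required (the system is
underdetermined below D = 4).  Permutations shuffle every feature's counts
independently and recompute the *full refined* estimator so p-values
reflect the actual statistic.

Per-cohort edges are combined by Fisher's method (−2Σln p ~ χ²_2k, k =
cohorts observed; exact zeros floored to the smallest positive float with a
warning) and the median correlation across cohorts; BH FDR runs across all
candidate pairs of one phenotype-group network; edges pass at FDR < 10⁻⁵
and |median r| > 0.3, tiered fair/moderate at 0.3/0.6.  Edges observed in
only some cohorts are combined over the available ones with the count
recorded.

Two practical notes.  Multinomial sampling noise adds independent variance
to every log-ratio and attenuates estimated correlations; the estimator
recovery experiment therefore simulates deep libraries (5×10⁵ reads) where
that noise is negligible, and uses a 5-feature block so the 20 exclusion
iterations can cover all of its pairs — larger blocks violate the sparsity
assumption faster than refinement can repair.  And the FDR < 10⁻⁵ gate
presumes the resolution of 1,000-permutation p-values and sizeable cohorts;
at the demo's scale (30 samples per cohort-group, 199 permutations) the
gate is rarely passable and the demo honestly reports empty networks.

## Diversity

Shannon −Σp ln p, Gini-Simpson 1 − Σp², Bray–Curtis Σ|u−v|/Σ(u+v), classical
PCoA by double-centering (negative eigenvalues reported, their axes
dropped), and a one-factor PERMANOVA with seeded free label permutation and
the plus-one p-value.  The two-factor design (group, cohort) is realized as
two separate one-factor tests.  The pseudo-F statistic is cross-checked
against scikit-bio in the tests; the in-package implementation exists to
provide seeded permutations and the R² = SS_between/SS_total decomposition
in one place.  A covariate-adjusted OLS of Shannon on group, cohort and the
discretized covariates stands in for mixed-model alpha-diversity testing,
which is out of scope.

## Functional analysis

Group (pathway/orthology) abundance is the plain sum of member-gene
relative abundances — a gene in k groups contributes fully to all k, and
sums are not renormalized at aggregation time (the differential pipeline
renormalizes per sample internally, which is the analysis scale).
Differential testing of groups reuses the full taxon pipeline unchanged.
Species–function association is a flat all-against-all Spearman screen with
BH FDR < 0.01; constant vectors are skipped with a note.  Hierarchical
block-association discovery is deliberately out of scope.

## Reproducibility

Every stochastic stage derives its seed from one master seed through named
substreams (`utils.substream_seed`), so changing one stage's randomness
never perturbs another's, and rerunning a configuration bit-reproduces all
deterministic outputs (the run manifest records config, seeds and file
digests).  The demo configuration reduces permutation counts, CV repeats,
forest sizes and the Boruta cap so the whole study runs in minutes on one
CPU; the package defaults are the full-scale analysis values
(999/1,000 permutations, 20×5 CV, Boruta cap 1,000, FDR 10⁻⁵).

## Known limitations

* The generator's log-linear covariate effects and single-shift batch model
  are simpler than real technical variation; batch-correction efficacy on
  real data will be lower.
* Fixed-effects pooling assumes one common effect; strongly heterogeneous
  cohorts (high I²) are flagged but not down-weighted (random-effects
  pooling is out of scope).
* Normal-theory pooled p-values are mildly anti-conservative at small
  per-cohort sample sizes (see Differential abundance above).
* Network recovery degrades with shallow sequencing, high zero-inflation
  and dense correlation structure; the estimator is consistent only under
  sparsity of true associations.
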