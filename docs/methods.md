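# Methods

`omicsforest` implements a three-step strategy for relating quantitative
traits to multi-omics profiles in a segregating mapping population, plus a
synthetic-study generator used to validate every stage.

## 1. Random-Forest feature selection with a permutation null

Each trait is regressed on one omics layer at a time (features x samples,
processed intensities) with a regression forest. Two quantities are read
off the fit:

- **OOB R²** = `1 − MSE_oob / Var(y)`, computed on out-of-bag samples only
  (each sample predicted by the trees whose bootstrap missed it). This is a
  predictive quantity, not a goodness-of-fit, and can be negative; it is
  reported as-is and only clipped for display percentages.
- **Impurity importance** per feature: the total decrease in node residual
  sum of squares attributed to splits on that feature, averaged over trees
  (per-sample scale). The permutation-importance alternative is deliberately
  not used.

The forest alone gives no significance levels, so a permutation test is
wrapped around it: in each of `n_perm` permutations of the trait vector
(features untouched) a fresh forest is fit and both its OOB R² and the full
importance vector are recorded. The model is declared significant when its
observed OOB R² exceeds the `1 − alpha_model` quantile of the null R²
distribution; only then are individual features selected, as those whose
importance exceeds the `1 − alpha_feature` quantile of the *pooled* null
importance distribution (all features x all permutations). A per-feature
null is available behind a flag; pooled is the default because importances
of exchangeable noise features share a common null scale. Selected subsets
are refit with a fresh forest to quantify the variance the reduced set
explains; subsets from several layers can be column-concatenated (feature
namespaces `Gene_/LC_/GC_/Pro_` keep IDs globally unique) and refit jointly.

Defaults: `n_trees = 1000`, candidate features per split `⌊p/3⌋` (the
classical regression-forest heuristic), minimum node size 5,
`n_perm = 1000`, `alpha_model = alpha_feature = 0.001`. All configurable;
every run logs its thresholds and seeds. Missing intensities are imputed
with the per-feature median before fitting; traits are used untransformed.

## 2. QTL mapping and representative selection

Trait and selected features are scanned marker-by-marker with the
single-marker linear model `value ~ genotype class`. In a diploid backcross
each marker segregates two classes (coded 0/1), so the scan statistic is a
two-group comparison: `LOD = (n/2)·log10(RSS0/RSS1)` with the p-value of
the equal-variance two-sample t-test (an exact identity used as the test
oracle). Implementation notes: markers with fewer than two informative
individuals in either class are skipped and flagged; missing genotypes are
dropped marker-wise; a perfect fit is capped at LOD 50; ties at the peak go
to the smallest cM position; the support interval is the conventional
1.5-LOD drop around the peak (contiguous markers).

Genome-wide significance is calibrated per phenotype by permutation: the
`1 − alpha` quantile of the maximum LOD over all markers across `n_perm`
permutations (scans are fully vectorized, so per-feature thresholds are
cheap). One QTL is called per linkage group whose maximum exceeds the
threshold. A feature whose QTL lies on the same linkage group as its
annotated physical position is **cis**-acting, on a different group
**trans**, and **unknown** when unannotated — deliberately at
linkage-group granularity, not a cM window.

Co-localization with the trait is likewise at linkage-group level. For
each omics layer and each linkage group carrying a trait QTL, the single
significant feature with a QTL there and the highest RF importance is kept
as the representative (ties: higher peak LOD, then lexicographically
smallest feature ID), giving at most one feature per layer per chromosome.
The representatives are refit as a compact predictor set.

## 3. Lasso-regularized partial-correlation network

Trait plus representatives are standardized (mean 0, population variance 1)
and modelled as a multivariate Gaussian. The precision matrix Ω maximizes
`log det Ω − tr(SΩ) − λ·Σ_{i≠j}|Ω_ij|` (graphical lasso; at λ = 0 the
inverse sample covariance, requiring n > p). Full-order partial
correlations follow as `ρ_ij = −Ω_ij/√(Ω_ii Ω_jj)`; edges exist where
`|ρ| > 1e-8`, signed for rendering (solid positive, dotted negative). The
trait node is penalized like every other node.

λ is selected by EBIC (γ = 0.5) over a log grid (default 0.01–1, 15
points): `EBIC = −2·loglik + E·log n + 4γE·log p` with `E` the edge count.
The likelihood is evaluated at the *unpenalized* MLE constrained to the
selected support (computed by the classical covariance-selection
regression iteration), not at the shrunk lasso estimate — scoring the
shrunk estimate empirically degenerates to the smallest grid penalty and
retains indirect edges. K-fold cross-validated predictive likelihood is
available as an alternative criterion. Because the edge set depends on λ,
the selected value is stored in the graph metadata and every export.

Caveat observed during design: when direct links are very strong
(pairwise r ≳ 0.85), the L1 penalty on the large precision entries induces
a compensating nonzero entry on the indirect pair, so chain recovery is
only assessed at moderate link strengths (r ≈ 0.7), which is also the
regime typical of omics correlations.

## The synthetic generator

The generator emulates a diploid backcross mapping population of the kind
the pipeline targets: 12 linkage groups of evenly spaced markers; per
linkage group a Markov chain of 0/1 genotypes with Haldane recombination
`r = (1 − e^{−2d/100})/2` between adjacent markers (no interference;
groups independent; class-1 frequency ½). On top of the genotypes it
plants:

- **cis features**: `feature = effect·genotype(driver) + N(0, sd)`,
  annotated with the driver's linkage group;
- **trans features**: same construction, annotated on a different group;
- **pathway chains**: each element a noisy linear function of its
  predecessor (transcript → metabolite → metabolite, transcript →
  protein), annotated `unknown` (metabolites have no physical position);
- **noise features**: pure Gaussian, in blocks of order 10²–10³ per layer
  (transcript layer largest, mirroring microarray scale);
- **the trait**: a sum of direct marker effects *and* of contributions
  routed through planted features (`trait_feature_effects`), plus
  Gaussian noise. The feature-routed form — genotype → expression →
  trait — is the default architecture, because it is the causal structure
  genetical genomics assumes: a trait determined by the activity of a few
  gene products, each of which is itself under genetic control. Routing
  the trait only through markers (independent of the features' residual
  noise) caps the feature–trait correlation near 0.3 regardless of effect
  size and makes any feature selector look broken.

Default architecture: 96 individuals, trait downstream of three cis
transcripts (coefficients 0.8/0.7/0.6, unit trait noise) plus one direct
QTL with an unmeasured mediator, one trans transcript, two pathway chains,
and noise blocks gene 2000 / LC 230 / GC 135 / protein 150. A configurable
fraction of planted features is annotated `unknown`.

What the generator does **not** emulate: intensity-dependent measurement
error, batch/year effects, heavy-tailed or skewed intensity distributions,
correlated noise blocks, segregation distortion, genotyping error,
epistasis, or F2/outbred designs. Passing tests therefore demonstrate the
statistical machinery under clean Gaussian conditions, not robustness to
real-data artefacts.

## Validation experiment sizes

The validation suite (and `scripts/acceptance.py`) uses these problem
sizes, chosen to give stable Monte-Carlo estimates at desk scale:

- permutation-test calibration: 100 replicate null datasets (n = 100,
  p = 500), `n_perm = 200`, α = 0.05, with a light forest (20 → 15 trees,
  ~20–25 candidate features). Calibration of the permutation test is exact
  by exchangeability for any fixed forest configuration, so forest size
  only affects runtime here.
- planted recovery: 10 seeds, n = 150, 5 causal features with standardized
  effect 2 among 500 noise, `n_perm = 100`, 60 trees.
- QTL oracle: 50 random small fixtures; genome-wide calibration on 100
  replicates (5 groups x 8 markers, n = 100, `n_perm = 200`).
- network: λ = 0 inversion oracle at n = 60, p = 5; chain recovery over
  10 seeds at n = 96.
- end-to-end: 10 seeds, n = 150, 12 groups x 6 markers, trait downstream
  of three cis transcripts, `n_perm = 100` (RF) / 150 (QTL).

## Known limitations

- Single-marker scans only: no interval or composite-interval mapping, no
  multi-QTL models; closely linked QTLs merge into one call per group.
- The pooled importance null assumes features are on comparable intensity
  scales within a layer; grossly heteroscedastic layers should be
  standardized first.
- EBIC consistency degrades for n ≪ p networks; the network stage is meant
  for the small representative sets (tens of nodes), not whole layers.
- With 1000-permutation nulls the α = 0.001 thresholds sit at the extreme
  of the null sample and are correspondingly noisy; the logs report both
  the 0.95 and the configured quantile.
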