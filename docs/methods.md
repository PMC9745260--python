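# Methods

This note describes the statistical models implemented in `rguc-kit`, the
choices made where a method admits more than one reading, and what the
synthetic data generator does and does not emulate.

## Setting

The toolkit targets range-wide surveys of dominant binary markers
(AFLP-style band presence/absence) scored on individuals partitioned into
populations, with population coordinates and bioclimatic raster layers as
covariates. Dominant markers hide heterozygotes, so every quantity is
defined either directly on band (phenotype) frequencies or on allele
frequencies recovered from band-absence frequencies (see below). Three
stages share this substrate:

1. **In-situ prioritization** — which and how many populations must be
   protected to retain a target share of total genetic diversity.
2. **Ex-situ design** — what mixture of populations maximizes the gene
   diversity of a pooled seed bank.
3. **Landscape projection** — how genetic composition turns over along
   climatic gradients, mapped under current and future climates.

## Diversity and rarity descriptors

- **Nei's gene diversity** per population is, by default, the band-phenotype
  form: mean over all loci of `n/(n-1) · 2f(1-f)` with `f` the
  within-population carrier frequency and `n` the population size. This is
  the convention of the AFLPdat toolkit for dominant data. An alternative
  allele-frequency route (`method="allele"`, square-root estimator) is
  provided because published tables rarely state which was used; the two
  differ systematically (the allele form is larger at moderate `f`), so the
  choice is an explicit argument, with the phenotype form as the documented
  default.
- **DW (frequency down-weighted marker value)** sums, over bands, the
  population's share of the band's total occurrences. Shares of any present
  band sum to 1 across populations, so DW is a partition of band "rarity
  mass"; a private band contributes exactly 1 regardless of its count.
- The map view of these descriptors uses plain inverse-distance weighting
  (power 2, exact at population cells). It is intended for visual
  inspection only — no statistic downstream consumes it.

## Structure diagnostics

- **Mantel test**: Pearson correlation of individual-pairwise genetic
  distance (proportion of mismatched loci) against `ln(km + 1)` great-circle
  distance (haversine, R = 6371 km; the +1 guards zero distances between
  individuals of one population). Significance comes from permuting
  individuals, one-sided for positive association, with the `(k+1)/(m+1)`
  convention so p is never 0.
- **Spatial autocorrelation** reports `A_y`, the mean genetic distance among
  pairs falling in each geographic distance class. Classes are equal
  pair-count bins: the class construction of the original
  alleles-in-space-style analysis is ambiguous, and equal counts guarantee
  no class is empty. Per-class two-sided p-values permute genotypes among
  locations with class membership fixed.
- **Φ_ST** is estimated by AMOVA on squared Euclidean distances between
  binary phenotypes (equal to mismatched-band counts), with the classical
  variance-component estimators and an unbiased-style `n̄` for unequal
  sample sizes. Negative estimates are reported as-is. The permutation test
  shuffles individuals among populations.
- Bayesian spatial clustering is **not** reimplemented: cluster labels are
  an input column of the population metadata. A seeded k-means on
  population band-frequency vectors (50 restarts, silhouette-chosen K when
  unspecified) serves as a surrogate so synthetic pipelines run end to end.

## Rare-band sampling theory

A band is *rare* when its overall carrier frequency is strictly below 10%
and it occurs in strictly fewer than 40% of populations (both thresholds
configurable; stricter published alternatives are 10%/10% and 10%/20%).

- **Loss probability** `L = (1-p)^(2N)` for a band at frequency `p` present
  in `N` populations. `p` is taken as the mean carrier frequency across the
  *occupied* populations — the same quantity used as the regression
  abscissa — because the loss model concerns the band where it exists.
  Using the overall frequency instead would mix the occupancy effect into
  `p`; this reading is a documented choice, not printed in the source
  material.
- **R-value**: ordinary least squares (with intercept) of `−ln L` on mean
  band frequency, once with observed occupancies (`L_o`) and once with
  `N = 1` (`L_e`, the "sample one population" scenario). R is
  `slope_e / slope_o`, so R ∈ (0, 1] and equals exactly `1/N` when all
  bands share occupancy `N`. Note the two conventions in circulation — the
  ratio written observed-over-expected would exceed 1; the implementation
  follows the interpretation of R as the *proportion of rare bands captured
  by sampling a single population*, which requires expected-over-observed.
- **Population count**: solving `P = 1 − F_ST^n` gives
  `n = ln(1−P)/ln(F_ST)`; integer recommendations always round **up**. The
  default retention target is `P = 0.999`. (A well-known published
  application states a 99% target in its methods yet reports `n = 4.94`
  for `F_ST = 0.247`, which is the 99.9% solution — `P = 0.99` would give
  3.29. The formula is exposed with `P` explicit so either target can be
  used.)
- **PSA (preferred sampling area)**: each rare band is assigned to the
  genetic cluster maximizing the fraction of the cluster's populations that
  carry it; ties break by carrier count in the cluster, then by lower
  cluster index. All tie-breaks are deterministic.
- **Optimal sampling proportions** per cluster combine the PSA share and the
  cluster R-values. No canonical combination rule exists in the literature
  we follow; the default is the arithmetic mean of the normalized PSA share
  and the normalized R-value, renormalized. The rule is pluggable
  (`strategy=` callable) and the result is labeled with the strategy used.
  On the published example inputs the default yields (0.391, 0.286, 0.323)
  against a reported (0.38, 0.28, 0.34) — close but not identical, which is
  expected given the unpublished rule.
- **RGUC selection** takes the top-`n` populations per cluster by Nei gene
  diversity (DW breaks ties, then label order) and reports the percentage
  of all bands and of rare bands captured, against a baseline that samples
  `n` populations per cluster uniformly at random (default 100 repetitions,
  seeded).

## Seed-bank optimization

- **Allele frequencies** from dominant data use the square-root
  (null-homozygote) estimator `q = sqrt(1 − f_band)`, by default with the
  Lynch–Milligan small-sample Taylor correction
  `q = sqrt(x)/(1 − Var(x)/(8x²))`, `Var(x) = x(1−x)/n` (applied only where
  the correction factor stays above 0.5; elsewhere the raw root is used).
  Loci fixed for band presence in a population are clamped to allele
  frequency `1/(2n+1)` and logged.
- **Coancestry** `f_ij` is the mean over loci of `p_i p_j + q_i q_j` — the
  probability of identity of two alleles drawn one from each population.
  Self-coancestry `f_ii` is the uncorrected expected gene identity; whether
  the reference contribution-analysis software corrects it for sample size
  is not recoverable, so the plain form is the documented default.
- **D_max** maximizes pooled diversity `1 − c'Fc` over the contribution
  simplex by projected-gradient descent (step `1/(2‖F‖₂)`, Euclidean
  simplex projection) from 100 random Dirichlet starts plus the uniform
  start, keeping the best. The problem is a convex QP whenever `F` is
  positive semidefinite (true for coancestry matrices built as above), so
  restarts are insurance, not necessity; the optimizer is verified against
  a 0.01-resolution simplex grid search on small instances.
  Contributions below 1e−6 are reported as exact zeros and the rest
  renormalized. A "synthetic pool" size (default 1000) only sets the
  granularity of reported seed counts.
- **Leave-one-out contributions**: with `H_S` the mean within-population
  expected heterozygosity and `D̄` the mean pairwise Nei minimum distance
  (`D_ij` = mean over loci of `[(p_i−p_j)² + (q_i−q_j)²]/2`), the
  contribution of population *i* is `100·(X_all − X_without_i)/X_all` for
  each indicator. Positive values mean the indicator *drops* when the
  population is removed; negative values are legitimate and are not
  clamped. The total is the sum of the two parts by construction
  (verified to 1e−6).

## Genotype–environment turnover

- **Collinearity filter**: iterative pairwise screening at `R² = 0.7` —
  while any pair of predictors exceeds the threshold, drop the member of
  the worst pair with the larger mean R² against the remaining predictors
  (ties drop the later column). Deterministic.
- **Turnover model**: one random-forest classifier per polymorphic locus
  (default 500 trees), responses at the individual level, predictors
  attached to individuals by population. A locus is retained when its
  out-of-bag error is strictly below the majority-class null error; an
  additional absolute error ceiling (e.g. 0.5) is exposed as
  `max_oob_error` because both retention styles appear in applied work.
  Split impurity improvements of retained loci are aggregated per predictor
  into 200 fixed-width bins over the predictor's training range, weighted
  by the locus's out-of-bag skill `1 − err/null`; the reference
  gradient-forest density standardization is deliberately simplified to
  this fixed-width binning. Cumulative sums give monotone, right-continuous
  *cumulative importance* functions scaled so each curve tops out at the
  predictor's overall importance (mean weighted split-importance share
  across retained loci).
- **Transform**: an environmental value maps to its predictor's cumulative
  importance at that value; values outside the training range clamp to the
  endpoints (0 below, total importance above) with the clamp count logged.
- **Maps**: PCA is fitted on the transformed grid cells; populations are
  projected into that space, Ward-clustered, and cut at the requested
  number of groups (default 3); every pixel joins the nearest group
  centroid in the leading PCA axes. Future scenarios are transformed,
  averaged per pixel across climate models, and assigned with the PCA and
  centroids **frozen** from the current-climate fit, so group identities
  are comparable across time slices.

## Synthetic data generator

The generator emulates the statistical shape of a range-wide AFLP survey
of a structured Mediterranean conifer: by default 11 populations in K = 3
clusters with sample sizes (24, 23, 26, 24, 25, 17, 18, 23, 24, 24, 27),
203 loci, an AMOVA differentiation target of 0.247, ~30% rare bands, and
10 climate-linked loci, on a 0.4° grid spanning 9°W–7°E, 30–38°N.

- **Drift**: population band frequencies follow a two-level
  Balding–Nichols beta hierarchy (ancestral → cluster → population), with
  the drift split between levels by `cluster_share` (default 0.5).
  Because rare and climate-linked loci carry their own (mostly weak)
  differentiation, the neutral drift parameter is solved analytically so
  the *expected whole-matrix* AMOVA ratio equals `fst_target`; the
  realized Monte-Carlo Φ_ST stays within ±0.05 of the target for
  populations of ≥20 individuals.
- **Drift heterogeneity**: populations receive lognormal drift multipliers
  (σ = 0.5). Populations with weak drift both retain diversity and are
  preferentially chosen to host rare bands (weights ∝ drift⁻²) — the
  empirical association that makes diversity-ranked selection informative
  about rarity capture, as observed in real surveys.
- **Rare bands** are seeded in a home cluster first, with expected overall
  frequency capped at 60% of the rarity threshold; after Bernoulli
  sampling the realized frequency and occupancy are re-checked and
  violating loci resampled.
- **Climate-linked loci** follow a logistic function (slope `beta`, default
  2) of the standardized value of one designated layer at the population.
- **Climate layers** are random low-order spatial trends plus
  Gaussian-smoothed noise, unitless. They are *not* calibrated to real
  WorldClim marginals, carry no cross-layer correlation structure beyond
  chance, and the landscape has no coastline mask.
- All randomness flows from one seed through `SeedSequence` spawning; a
  repeated run is bit-identical, and the band matrix and climate stack can
  be regenerated independently yet consistently.

What passing tests on this generator do **not** show: performance under
genotyping error or missing data, linkage between loci, coalescent noise,
isolation-by-distance within clusters, or realistic climate covariance.
The generator is a statistical emulator, not a demographic simulator.

## Numerical and I/O choices

- Rasters are read and written as ESRI ASCII grids (cell-centered,
  row-major from the NW corner, union nodata mask across layers) — a
  plain-text format every GIS ingests.
- Band matrices are comma- or tab-delimited 0/1 text; missing cells are
  rejected at load unless imputation from rounded population means is
  explicitly requested (each imputation is reported).
- Permutation p-values use the `+1/(n+1)` convention throughout.
- Test-suite and verification problem sizes are scaled down from the
  full-survey defaults (tens of loci, ~10 individuals per population,
  ~100 trees per forest) — chosen so the distributional properties under
  test are still resolvable while the whole suite runs in minutes.

## Known limitations

- Φ_ST uses a single hierarchical level (populations within total);
  cluster/population nesting is available only by merging labels.
- The turnover model's importance curves are binned approximations; exact
  numerical parity with the reference gradient-forest implementation is
  not a goal and was not attempted.
- The optimal-proportion combination rule is heuristic by necessity (see
  above) and should be treated as a reporting aid, not an estimator.
- With fewer than ~5 populations per cluster the cluster-level R-value
  regressions are fragile; the pipeline falls back to the species-wide
  R-value when a cluster has too few rare bands to regress.
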