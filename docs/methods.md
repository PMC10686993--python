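# Methods

This note records the models implemented in `geoadapt`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when comparing output
against other software.

## Synthetic study design

The generator (`geoadapt.synthdata`) emulates a two-wave end-glacial
colonization sampled along a one-dimensional transect:

- **Ancestry.** Population mean ancestry follows a logistic cline in the
  site index (softmax of negative distances to K evenly spaced centers;
  for K=2 this is exactly logistic). Default steepness 8 puts endpoint
  populations at ~0.9997 mean majority ancestry, i.e. effectively pure
  sources at the cline ends, with a smooth admixture gradient between.
  Individuals draw Dirichlet around the population mean (concentration 50,
  tight but not degenerate).
- **Neutral genotypes.** Balding–Nichols: each source's allele frequency
  is Beta-distributed around a shared ancestral p ~ U(0.05, 0.95) with
  differentiation parameter `fst_drift` (default 0.2, moderate continental
  divergence). An individual's expected frequency mixes source frequencies
  by its ancestry; genotypes are Binomial(2, freq). The model is
  closed-form and dependency-free; it deliberately omits linkage — loci
  are exchangeable and unlinked, so LD pruning has nothing to do and
  window-based methods are out of scope.
- **Climate.** Four variables (named after the bioclim set they imitate:
  annual mean temperature, isothermality, max temperature of the warmest
  month, annual precipitation) are fixed mixtures of four standardized
  latent fields (N-S ramp, radial bowl, a 1.5-cycle N-S wave, a tilted E-W
  ramp) plus 5% white noise, rescaled to plausible physical units. The
  mixture weights were chosen once so that site-level pairwise
  correlations land at |r| ≈ 0.4–0.5 and VIF < 2 — the regime of a curated
  bioclim subset in which an r < 0.7 / VIF < 10 screen retains all
  variables. Sites sit on a south-to-north transect with an east-west
  wiggle so non-latitudinal fields also vary across sites.
- **Adaptive loci.** A chosen number of loci (default 100 of 2000) are
  coupled round-robin to the variables: the logit of the individual-level
  expected frequency shifts by `beta` × (site-standardized variable value),
  default beta = 1.5 per environmental SD — strong enough for partial
  power at n = 120, weak enough that no single scan saturates. Coupling on
  the logit keeps frequencies in (0,1) smoothly; values pushed past
  [1e-6, 1−1e-6] are clipped and counted.
- **Future climate.** Default: each variable shifts by `future_shift`
  (default 1) spatial SDs, uniformly. With `future_pattern="gradient"` the
  shift scales with latitude (0.25–1.75×), giving a spatially varying true
  displacement against which offset surfaces can be rank-correlated.
- **Missingness** is injected uniformly at random (default 2%). The
  missingness pattern of real post-filter call sets is unknown to us and
  is unlikely to be uniform; tests passing under this assumption say
  nothing about structured missingness (e.g. depth-correlated).

One `numpy` Generator seeded from `config.seed` drives everything; a
bundle is bit-reproducible and its manifest records the config and seed.

What passing tests on these fixtures show: the estimators recover the
structure the model family assumes (independent loci, binomial sampling,
linear climate coupling on the logit). What they do not show: robustness
to LD, allele-frequency spectra from real demography, genotyping error,
or structured missingness.

## Filtering

MAF > 5%, missingness < 10%, and a per-population 1-df chi-square HWE test
at α = 0.001 (tested only where a population has ≥5 genotyped individuals
and both alleles). The "out within" convention is ambiguous for a
rectangular matrix: the default drops a SNP genome-wide when it fails HWE
in any population (preserving matrix shape for ordination); a lenient
mode masks genotypes in the offending population only. The chi-square was
chosen over an exact test to stay inside scipy; at the sample sizes
involved (≥5 per population, tested loci polymorphic) the 1-df chi-square
is adequate, and an exact-test hook can be added behind the same
interface.

## Population structure

- **PCA**: Patterson scaling (center 2p̂, scale √(p̂(1−p̂))), per-locus
  mean imputation of missing dosages, SVD; eigenvalues are squared
  singular values over n−1.
- **F_ST**: Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals within), c (within individuals),
  computed per locus from per-population sample sizes, allele and
  heterozygote frequencies. Pairwise values use the ratio-of-sums across
  loci; the per-SNP scan uses the per-locus ratio with undefined loci
  (monomorphic, empty denominator) excluded from percentile flagging.
- **Admixture**: EM block updates of Q and F for the binomial likelihood.
  EM reaches the same stationary points as quasi-Newton block relaxation
  but is simpler and monotone in the likelihood (asserted in tests);
  restarts (library default 5) mitigate local optima. This is a
  behavioral, not bit-level, reimplementation of the standard tool. The
  library default tolerance is Δℓ < 1e-6 with up to 2000 iterations; the
  pipeline and tests use lighter budgets (tol 1e-4 or 1e-3, 150–500
  iterations, 1–3 restarts) appropriate to fixture-scale problems, since
  ancestry estimates stabilize to ~0.01 mean absolute error long before
  the strict tolerance is met.
- **Choice of K**: masked-entry cross-validation — hide 10% of non-missing
  genotype entries, refit, score hidden entries by binomial deviance under
  ĥ (clipped away from {0,1} so the deviance is finite). This replaces
  fold-based CV machinery whose loss is not precisely documented; with a
  different loss the selected K on borderline data could differ.

## Ordination

`fit_rda(Y, X, Z)` centers Y, residualizes Y and X on [1, Z] when Z is
given (conditioning on an empty matrix is exactly the identity), fits
Ŷ = X_res B by least squares and takes the SVD of Ŷ. Canonical
eigenvalues are singular values squared over n−1; site scores are the
fitted ("lc") scores U·S; response loadings are right singular vectors;
predictor scores are correlations of residualized predictors with site
scores. The constrained / conditioned / residual fractions decompose
trace(YᵀY) exactly (checked to 1e-10). Rank-deficient predictor blocks go
through the pseudo-inverse with the rank reported.

Variance partitioning fits the full model plus three pRDAs (each block
conditioned on the other two). The confounded fraction is full minus the
sum of pure fractions and may be negative (suppression); it is reported,
never clamped. Permutation significance permutes rows of the conditioned
response residuals; F uses rank(X) and n − 1 − rank(Z) − rank(X) degrees
of freedom.

Response rows are individuals by default (dosage matrix), with site-level
covariates broadcast to individuals; a population-frequency response can
be passed instead since all entry points accept plain arrays. One
ancestry column is dropped from conditioning (simplex collinearity);
geography enters as raw (lat, lon) with no spatial polynomials.

## Genome scans

The scan ordination uses Patterson-scaled dosages so SNP loadings are
comparable across allele frequencies; without this the loading
distribution is a variance mixture and its Mahalanobis distances are
heavy-tailed relative to χ². (Variance partitioning, by contrast, runs on
centered raw dosages, the convention under which "percent of genetic
variance" is usually quoted.)

Both Mahalanobis scans use a robust location/scatter: columns centered by
the median and scaled by 1.4826·MAD, then a Ledoit–Wolf shrinkage
covariance; minimum covariance determinant is available as an option. The
genomic inflation factor λ = median(D²)/median(χ²_df) is computed on all
tested SNPs; a degenerate all-zero scan (λ = 0) returns p = 1 everywhere.
Percentile ties at the F_ST threshold are excluded by the strict
inequality and logged. q-values use Storey's π̂₀ at λ = 0.5 (bounded to
≤1) with the step-up minimum; BH is the π₀ = 1 special case.

On null fixtures (beta = 0) both scans pass KS uniformity at α = 0.01 with
λ within [0.9, 1.1], and the three-way intersection is empty across 20
seeds — the calibration that justifies interpreting the intersection as
high-confidence candidates.

## Offsets

The adaptively enriched SNP set (q_RDA < 0.05) is ordinated on the
standardized climate variables (unconditioned by default; a conditioned
mode exists). The fitted environmental axis scores and the fit-time
standardization (mean, SD per variable) define the adaptive index of any
pixel; a pixel at the fit-site mean of every variable scores exactly 0 on
every axis.

- **Genomic offset** sums per-axis |ΔAI| between current and future
  climate (L1 over axes). The L1 sum is the default because per-axis
  displacements are aggregated after the absolute value, making the
  statistic an exact pseudometric per axis; Euclidean-over-axes and
  eigenvalue-weighted variants are selectable since the aggregation
  convention is genuinely open.
- **Geographic offset** finds, for each pixel, locations whose current AI
  vector lies within a Euclidean tolerance of the pixel's future AI, and
  returns the minimal haversine distance; an empty match set yields a
  counted "no-analog" sentinel. The equivalence tolerance has no canonical
  value; the default is 5% of the mean per-axis range of the current
  index, and both pixel-set and sampled-population match modes are
  provided because either could be meant by "nearest population".
- **SGV** is the mean over candidate loci of p(1−p) within a population
  (bounded by 0.25 at p = 0.5, 0 at fixation) — the per-population reading
  of "mean variance of allele frequencies"; the alternative reading (mean
  across-population variance per locus) is exposed as a mode. **PAI** is
  the mean |p_jl − p̄_l| with p̄ the unweighted cross-population mean.

On the cline fixtures, extreme-ancestry populations show higher PAI and
lower SGV than mid-cline admixed populations, and the genomic-offset
surface rank-correlates ≥ 0.8 with the true per-pixel climate
displacement under a latitude-graded shift — the qualitative pattern this
class of analysis is meant to surface.

## Pipeline and problem sizes

`run_pipeline` executes ingest → filter → variable selection → structure →
variance partition → scans → intersection → enriched ordination → offsets,
persisting every intermediate and a manifest (config hash, seed, package
version, per-stage counts). Two runs with the same config and seed produce
identical manifests up to timings. Defaults: FDR 0.1, enriched FDR 0.05,
F_ST percentile 95, three retained axes, 199 permutations.

Fixture-scale defaults (12 populations × 10 diploids, 2000 SNPs, 20×20
raster) were chosen as the smallest design in which all estimators are
comfortably identified: ≥2 populations per ancestry regime, enough loci
for percentile thresholds and q-value estimation to be meaningful, and a
raster fine enough for offset surfaces to vary smoothly. The full test
suite and the acceptance script each complete in well under a minute on a
single CPU at these sizes.

## Known limitations

- No linkage: window-based pruning and haplotype statistics are out of
  scope; the optional r² pruning pass is a plain greedy filter.
- The admixture EM, robust-covariance scans and CV loss are behavioral
  reimplementations — numerically sensible but not bit-compatible with
  ADMIXTURE, pcadapt, or any specific q-value implementation.
- Geographic offset is O(P²) in valid pixels; fine to ~10⁴ pixels, after
  which the population match mode is the practical choice.
- Individual-row versus population-row ordination is a documented choice;
  results on strongly unbalanced sampling will differ between modes.
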